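import numpy as np
import pytest

from barcodecmp.evodist import (
    InestimableDistanceError,
    SiteCounts,
    _tn93_rate_matrix,
    evolutionary_matrix,
    k2p,
    mcl_matrix,
    pairwise_counts,
    tajima_nei,
    tamura3,
    tn93,
)
from barcodecmp.seqdata import Sequence, SequenceSet

from tests.helpers import BASES


def make_counts(P1=0.0, P2=0.0, Q=0.0, g=(0.25, 0.25, 0.25, 0.25), gc=None, F=None):
    """SiteCounts with a consistent mismatch matrix for formula checks."""
    g = np.asarray(g, dtype=float)
    if F is None:
        # distribute the stated proportions over a plausible F
        F = np.diag(g * (1 - P1 - P2 - Q))
        F[0, 2] = F[2, 0] = P1 / 2
        F[1, 3] = F[3, 1] = P2 / 2
        for i, j in ((0, 1), (0, 3), (2, 1), (2, 3)):
            F[i, j] = F[j, i] = Q / 8
        F /= F.sum()
    gc1 = gc if gc is not None else float(g[1] + g[2])
    return SiteCounts(n=1000, P1=P1, P2=P2, Q=Q, g=g, gc1=gc1, gc2=gc1, F=np.asarray(F))


class TestPairwiseCounts:
    def test_manual_column_enumeration(self):
        c = pairwise_counts("ACGT", "GCGA")
        assert c.n == 4
        assert c.P1 == pytest.approx(0.25)  # A<->G
        assert c.P2 == 0.0
        assert c.Q == pytest.approx(0.25)  # T<->A
        assert c.P == pytest.approx(0.25)

    def test_identical_sequences(self):
        c = pairwise_counts("ACGTACGT", "ACGTACGT")
        assert c.P == 0.0 and c.Q == 0.0

    def test_pairwise_deletion_of_ambiguous_columns(self):
        c = pairwise_counts("ACGN", "ACGA")
        assert c.n == 3
        assert c.P == 0.0 and c.Q == 0.0

    def test_gap_columns_removed(self):
        c = pairwise_counts("AC-T", "ACTT")
        assert c.n == 3

    def test_all_ambiguous_rejected(self):
        with pytest.raises(InestimableDistanceError):
            pairwise_counts("NNNN", "ACGT")

    def test_invariants_of_proportions(self):
        rng = np.random.default_rng(23)
        a = "".join(BASES[rng.integers(0, 4, 200)])
        b = "".join(BASES[rng.integers(0, 4, 200)])
        c = pairwise_counts(a, b)
        assert c.P == pytest.approx(c.P1 + c.P2)
        assert 0 <= c.P + c.Q <= 1
        assert c.g.sum() == pytest.approx(1.0)
        assert c.F.sum() == pytest.approx(1.0)
        assert np.allclose((c.F * c.n), np.round(c.F * c.n))


class TestClosedForms:
    def test_k2p_zero_on_identity(self):
        assert k2p(make_counts()) == 0.0

    def test_k2p_textbook_value(self):
        c = make_counts(P1=0.1, Q=0.05)
        expected = -0.5 * np.log(0.75) - 0.25 * np.log(0.90)
        assert k2p(c) == pytest.approx(expected, abs=1e-12)

    def test_k2p_saturated_pair_rejected(self):
        with pytest.raises(InestimableDistanceError):
            k2p(make_counts(P1=0.5, Q=0.4))

    def test_tajima_nei_zero_and_jc_limit(self):
        assert tajima_nei(make_counts()) == 0.0
        # equal frequencies, uniform mismatch -> exactly Jukes-Cantor
        p = 0.06
        F = np.full((4, 4), p / 12)
        np.fill_diagonal(F, (1 - p) / 4)
        c = make_counts(P1=p / 3, P2=p / 3, Q=p / 3, F=F)
        jc = -0.75 * np.log(1 - 4 * p / 3)
        assert tajima_nei(c) == pytest.approx(jc, rel=1e-9)

    def test_tamura3_reduces_to_k2p_at_half_gc(self):
        c = make_counts(P1=0.08, P2=0.04, Q=0.06, gc=0.5)
        assert tamura3(c) == pytest.approx(k2p(c), rel=1e-12)

    def test_tn93_reduces_to_k2p_at_equal_frequencies(self):
        # with equal frequencies and P1 == P2 the TN93 terms collapse
        c = make_counts(P1=0.05, P2=0.05, Q=0.06)
        assert tn93(c) == pytest.approx(k2p(c), rel=1e-9)

    def test_tn93_gamma_approaches_plain_for_large_shape(self):
        c = make_counts(P1=0.05, P2=0.03, Q=0.06, g=(0.3, 0.2, 0.2, 0.3))
        assert tn93(c, gamma_shape=1e7) == pytest.approx(tn93(c), rel=1e-5)
        assert tn93(c, gamma_shape=0.5) > tn93(c)


class TestReferenceAgreement:
    """Frozen oracle values computed with ape::dist.dna (model K80,
    pairwise deletion) on the fixed 4-taxon alignment."""

    APE_K80 = {
        ("t1", "t2"): 0.149035602612283,
        ("t1", "t3"): 0.170181165140347,
        ("t1", "t4"): 0.276381701401079,
        ("t2", "t3"): 0.243532932891001,
        ("t2", "t4"): 0.359051188127401,
        ("t3", "t4"): 0.340530552287226,
    }

    def test_k2p_matches_ape_to_1e9(self, ref4_set):
        m = evolutionary_matrix(ref4_set, "K2P")
        idx = {lab: i for i, lab in enumerate(m.labels)}
        for (a, b), expected in self.APE_K80.items():
            assert m.values[idx[a], idx[b]] == pytest.approx(expected, abs=1e-9)

    def test_estimators_agree_with_independent_formula_evaluation(self, ref4_set):
        # literal textbook formulas recomputed here from raw column counts,
        # independently of the SiteCounts plumbing
        a = ref4_set[0].residues
        b = ref4_set[3].residues
        n = len(a)
        pairs = list(zip(a, b))
        ts = {"AG", "GA", "CT", "TC"}
        P = sum(1 for x, y in pairs if x != y and x + y in ts) / n
        Q = sum(1 for x, y in pairs if x != y and x + y not in ts) / n
        d_manual = -0.5 * np.log(1 - 2 * P - Q) - 0.25 * np.log(1 - 2 * Q)
        sc = pairwise_counts(a, b)
        assert k2p(sc) == pytest.approx(d_manual, abs=1e-12)

        gc1 = sum(1 for x in a if x in "GC") / n
        gc2 = sum(1 for x in b if x in "GC") / n
        c = gc1 + gc2 - 2 * gc1 * gc2
        d_t92 = -c * np.log(1 - P / c - Q) - 0.5 * (1 - c) * np.log(1 - 2 * Q)
        assert tamura3(sc) == pytest.approx(d_t92, abs=1e-12)

    def test_tamura3_tn93_near_ape_despite_parameterisation(self, ref4_set):
        # ape pools G+C and base frequencies differently from the
        # two-sequence form used here; agreement is close but not exact
        ape_t92_12 = 0.149618892802370
        ape_tn93_12 = 0.149659426627831
        mt = evolutionary_matrix(ref4_set, "Tamura3")
        mn = evolutionary_matrix(ref4_set, "TN93")
        assert mt.values[0, 1] == pytest.approx(ape_t92_12, abs=5e-3)
        assert mn.values[0, 1] == pytest.approx(ape_tn93_12, abs=5e-3)


class TestEstimatorProperties:
    def test_zero_on_identical_and_symmetric(self, ref4_set):
        for model in ("K2P", "TajimaNei", "Tamura3", "TN93"):
            m = evolutionary_matrix(ref4_set, model)
            assert np.array_equal(m.values, m.values.T)
            assert np.all(np.diag(m.values) == 0)

    def test_monotone_in_true_divergence(self):
        """Ancestor-descendant path: every estimator increases along it."""
        from tests.helpers import evolve_from, random_dna

        rng = np.random.default_rng(31)
        anc = random_dna(rng, 5000)
        chain = [anc]
        for _ in range(4):
            chain.append(evolve_from(rng, chain[-1], 0.06))
        for est in (k2p, tajima_nei, tamura3, tn93):
            ds = [est(pairwise_counts(anc, s)) for s in chain[1:]]
            assert all(a < b for a, b in zip(ds, ds[1:])), est.__name__


class TestMCL:
    def _simulate_star(self, d, n_taxa=4, length=10_000, seed=77, kappa=(6.0, 3.0)):
        """Taxa hanging off a star at pairwise distance d under TN93."""
        rng = np.random.default_rng(seed)
        pi = np.array([0.3, 0.2, 0.2, 0.3])
        q = _tn93_rate_matrix(*kappa, pi)
        from scipy.linalg import expm

        p = expm(q * (d / 2))
        cum = np.cumsum(p, axis=1)
        root = rng.choice(4, size=length, p=pi)
        seqs = []
        for t in range(n_taxa):
            u = rng.random(length)
            der = np.empty(length, dtype=np.int64)
            for s in range(4):
                mask = root == s
                der[mask] = np.searchsorted(cum[s], u[mask], side="right")
            seqs.append(Sequence(label=f"x{t}", residues="".join(BASES[der])))
        return SequenceSet(seqs)

    def test_identical_sequences_give_zero(self):
        seqs = SequenceSet([Sequence(label=f"s{i}", residues="ACGTAC" * 20) for i in range(3)])
        m = mcl_matrix(seqs)
        assert np.allclose(m.values, 0.0, atol=1e-6)

    def test_recovers_known_distance_within_5pct(self):
        d_true = 0.15
        seqs = self._simulate_star(d_true)
        m = mcl_matrix(seqs)
        est = m.values[np.triu_indices(len(m), k=1)]
        assert np.mean(est) == pytest.approx(d_true, rel=0.05)

    def test_collapses_to_k2p_at_equal_frequencies(self):
        rng = np.random.default_rng(55)
        # K2P is TN93 with equal frequencies and a single rate ratio
        pi = np.array([0.25, 0.25, 0.25, 0.25])
        q = _tn93_rate_matrix(4.0, 4.0, pi)
        from scipy.linalg import expm

        length = 20_000
        p = expm(q * 0.10)
        cum = np.cumsum(p, axis=1)
        root = rng.choice(4, size=length, p=pi)
        seqs = []
        for t in range(3):
            u = rng.random(length)
            der = np.empty(length, dtype=np.int64)
            for s in range(4):
                mask = root == s
                der[mask] = np.searchsorted(cum[s], u[mask], side="right")
            seqs.append(Sequence(label=f"x{t}", residues="".join(BASES[der])))
        sset = SequenceSet(seqs)
        m_mcl = mcl_matrix(sset)
        m_k2p = evolutionary_matrix(sset, "K2P")
        iu = np.triu_indices(3, k=1)
        assert np.allclose(m_mcl.values[iu], m_k2p.values[iu], rtol=0.03)
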