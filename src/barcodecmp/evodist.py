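"""Alignment-based evolutionary distance estimators.

Pairwise distances between aligned DNA sequences under progressively
richer substitution models: Kimura 2-parameter, Tajima-Nei (1984),
Tamura 3-parameter (1992), Tamura-Nei (1993), and the maximum composite
likelihood estimator in which all pairwise distances and the shared
TN93 substitution parameters are fitted jointly.

All estimators use pairwise deletion: for each pair, alignment columns
in which either sequence carries a gap or a non-ACGT character are
excluded before proportions are formed.  Saturated pairs for which a
logarithm argument becomes nonpositive raise
:class:`InestimableDistanceError` rather than returning an imputed value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize_scalar

from barcodecmp.compdist import DistanceMatrix
from barcodecmp.seqdata import SequenceSet

__all__ = [
    "SiteCounts",
    "InestimableDistanceError",
    "pairwise_counts",
    "k2p",
    "tajima_nei",
    "tamura3",
    "tn93",
    "evolutionary_matrix",
    "mcl_matrix",
    "EVO_MODELS",
]

# base order used throughout: A=0, C=1, G=2, T=3
_A, _C, _G, _T = 0, 1, 2, 3

_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _LUT[_c] = _i
    _LUT[_c + 32] = _i


class InestimableDistanceError(ValueError):
    """Raised when a distance formula's logarithm argument is nonpositive
    (saturated pair) or a required base frequency is zero."""


@dataclass(frozen=True)
class SiteCounts:
    """Pairwise site-pattern summary after pairwise deletion.

    ``F`` is the 4x4 joint observed-frequency matrix (rows: first
    sequence, columns: second), summing to 1 over the ``n`` retained
    sites.  ``g`` pools the base frequencies of both sequences.
    """

    n: int
    P1: float  # A<->G transition proportion
    P2: float  # C<->T transition proportion
    Q: float  # transversion proportion
    g: np.ndarray  # pooled base frequencies, length 4 (A,C,G,T)
    gc1: float
    gc2: float
    F: np.ndarray  # 4x4 joint observed frequencies

    @property
    def P(self) -> float:
        return self.P1 + self.P2


def _encode(s: str) -> np.ndarray:
    return _LUT[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]


def _counts_from_codes(a: np.ndarray, b: np.ndarray) -> SiteCounts:
    valid = (a < 4) & (b < 4)
    n = int(valid.sum())
    if n == 0:
        raise InestimableDistanceError("no comparable sites after pairwise deletion")
    av, bv = a[valid], b[valid]
    F = np.bincount(4 * av.astype(np.intp) + bv, minlength=16).reshape(4, 4) / n
    P1 = F[_A, _G] + F[_G, _A]
    P2 = F[_C, _T] + F[_T, _C]
    Q = (
        F[_A, _C] + F[_C, _A] + F[_A, _T] + F[_T, _A]
        + F[_G, _C] + F[_C, _G] + F[_G, _T] + F[_T, _G]
    )
    g = (F.sum(axis=1) + F.sum(axis=0)) / 2.0
    f1 = F.sum(axis=1)
    f2 = F.sum(axis=0)
    return SiteCounts(
        n=n,
        P1=float(P1),
        P2=float(P2),
        Q=float(Q),
        g=g,
        gc1=float(f1[_C] + f1[_G]),
        gc2=float(f2[_C] + f2[_G]),
        F=F,
    )


def pairwise_counts(a: str, b: str) -> SiteCounts:
    """Site-pattern counts for two aligned, equal-length sequences."""
    if len(a) != len(b):
        raise ValueError(f"aligned sequences differ in length: {len(a)} vs {len(b)}")
    return _counts_from_codes(_encode(a), _encode(b))


def _safe_log(x: float, what: str) -> float:
    if x <= 0:
        raise InestimableDistanceError(f"{what}: log argument {x:.6g} <= 0 (saturated pair)")
    return float(np.log(x))


def k2p(counts: SiteCounts) -> float:
    """Kimura 2-parameter distance: -0.5 ln(1-2P-Q) - 0.25 ln(1-2Q)."""
    P, Q = counts.P, counts.Q
    return -0.5 * _safe_log(1 - 2 * P - Q, "K2P") - 0.25 * _safe_log(1 - 2 * Q, "K2P")


def tajima_nei(counts: SiteCounts) -> float:
    """Tajima-Nei (1984) distance, the unequal-frequency correction of JC."""
    p = counts.P + counts.Q
    if p == 0:
        return 0.0
    g = counts.g
    F = counts.F
    h = 0.0
    for i in range(4):
        for j in range(i + 1, 4):
            x_ij = F[i, j] + F[j, i]
            if x_ij > 0:
                if g[i] == 0 or g[j] == 0:
                    raise InestimableDistanceError("Tajima-Nei: zero base frequency")
                h += x_ij**2 / (2 * g[i] * g[j])
    b = 0.5 * (1 - float(np.sum(g**2)) + p**2 / h)
    return -b * _safe_log(1 - p / b, "Tajima-Nei")


def tamura3(counts: SiteCounts) -> float:
    """Tamura 3-parameter distance (1992), correcting for G+C-content bias."""
    P, Q = counts.P, counts.Q
    if P == 0 and Q == 0:
        return 0.0
    c = counts.gc1 + counts.gc2 - 2 * counts.gc1 * counts.gc2
    if c == 0:
        raise InestimableDistanceError("Tamura-3: degenerate G+C content")
    return -c * _safe_log(1 - P / c - Q, "Tamura-3") - 0.5 * (1 - c) * _safe_log(
        1 - 2 * Q, "Tamura-3"
    )


def tn93(counts: SiteCounts, gamma_shape: float | None = None) -> float:
    """Tamura-Nei (1993) distance; optionally gamma-rate corrected.

    With ``gamma_shape`` = a, each -ln(w) term is replaced by
    a * (w**(-1/a) - 1), the standard gamma-distances transform.
    """
    if counts.P1 == 0 and counts.P2 == 0 and counts.Q == 0:
        return 0.0
    g = counts.g
    gA, gC, gG, gT = (float(v) for v in g)
    gR, gY = gA + gG, gC + gT
    if gA * gG == 0 or gT * gC == 0 or gR * gY == 0:
        raise InestimableDistanceError("TN93: zero base frequency in a denominator")
    P1, P2, Q = counts.P1, counts.P2, counts.Q
    w1 = 1 - P1 * gR / (2 * gA * gG) - Q / (2 * gR)
    w2 = 1 - P2 * gY / (2 * gT * gC) - Q / (2 * gY)
    w3 = 1 - Q / (2 * gR * gY)
    k1 = 2 * gA * gG / gR
    k2 = 2 * gT * gC / gY
    k3 = 2 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY)
    if gamma_shape is None:
        terms = [-_safe_log(w, "TN93") for w in (w1, w2, w3)]
    else:
        a = gamma_shape
        for w in (w1, w2, w3):
            if w <= 0:
                raise InestimableDistanceError("TN93: log argument <= 0 (saturated pair)")
        terms = [a * (w ** (-1.0 / a) - 1.0) for w in (w1, w2, w3)]
    return k1 * terms[0] + k2 * terms[1] + k3 * terms[2]


_ESTIMATORS = {
    "K2P": k2p,
    "TAJIMANEI": tajima_nei,
    "TAMURA3": tamura3,
    "TN93": tn93,
}

#: canonical model names accepted by :func:`evolutionary_matrix`
EVO_MODELS = ("K2P", "TajimaNei", "Tamura3", "TN93", "MCL")


def _encode_set(seqs: SequenceSet) -> np.ndarray:
    if not seqs.is_aligned:
        raise ValueError("evolutionary distances require an aligned sequence set")
    return np.stack([_encode(s.residues) for s in seqs])


def evolutionary_matrix(seqs: SequenceSet, model: str = "K2P") -> DistanceMatrix:
    """All-pairs evolutionary distance matrix for an aligned set."""
    key = model.upper().replace("-", "").replace("_", "")
    if key == "MCL":
        return mcl_matrix(seqs)
    if key not in _ESTIMATORS:
        raise ValueError(f"unknown evolutionary model {model!r}")
    est = _ESTIMATORS[key]
    mat = _encode_set(seqs)
    n = mat.shape[0]
    if n < 3:
        raise ValueError("need at least 3 sequences to build a distance matrix")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = est(_counts_from_codes(mat[i], mat[j]))
            d[i, j] = d[j, i] = max(v, 0.0)
    return DistanceMatrix(labels=seqs.labels, values=d, method=model)


# ---------------------------------------------------------------------------
# maximum composite likelihood


def _tn93_rate_matrix(kappa1: float, kappa2: float, pi: np.ndarray) -> np.ndarray:
    """TN93 generator, normalised to one expected substitution per unit time."""
    q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            rate = pi[j]
            if {i, j} == {_A, _G}:
                rate *= kappa1
            elif {i, j} == {_C, _T}:
                rate *= kappa2
            q[i, j] = rate
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -float(np.dot(pi, np.diag(q)))
    return q / mu


def _pair_loglik(d: float, q: np.ndarray, pi: np.ndarray, C: np.ndarray) -> float:
    p = expm(q * d)
    joint = pi[:, None] * p
    mask = C > 0
    if np.any(joint[mask] <= 0):
        return -np.inf
    return float(np.sum(C[mask] * np.log(joint[mask])))


def mcl_matrix(
    seqs: SequenceSet,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> DistanceMatrix:
    """Maximum composite likelihood distances under the TN93 model.

    The two transition/transversion rate ratios and all pairwise
    distances are estimated jointly by maximising the sum of pairwise
    log-likelihoods; base frequencies are pooled over the whole
    alignment.  Alternates closed-form-initialised per-pair distance
    updates with shared-parameter updates until the composite
    log-likelihood improves by less than *tol*.
    """
    mat = _encode_set(seqs)
    n = mat.shape[0]
    if n < 3:
        raise ValueError("need at least 3 sequences to build a distance matrix")

    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    counts = []
    for i, j in pairs:
        sc = _counts_from_codes(mat[i], mat[j])
        counts.append(sc.F * sc.n)

    pooled = np.zeros(4)
    for C in counts:
        pooled += C.sum(axis=1) + C.sum(axis=0)
    pi = pooled / pooled.sum()
    if np.any(pi == 0):
        raise InestimableDistanceError("MCL: a base is absent from the alignment")

    # initialise distances from the closed-form TN93 estimator
    dists = []
    for (i, j), C in zip(pairs, counts):
        sc = _counts_from_codes(mat[i], mat[j])
        try:
            d0 = max(tn93(sc), 1e-8)
        except InestimableDistanceError:
            d0 = 1.0
        dists.append(d0)
    dists = np.array(dists)

    kappa = np.array([4.0, 4.0])  # A<->G and C<->T rate ratios

    def total_ll(k1: float, k2: float, ds: np.ndarray) -> float:
        q = _tn93_rate_matrix(k1, k2, pi)
        return sum(_pair_loglik(d, q, pi, C) for d, C in zip(ds, counts))

    ll = total_ll(kappa[0], kappa[1], dists)
    for _ in range(max_iter):
        q = _tn93_rate_matrix(kappa[0], kappa[1], pi)
        # per-pair distance updates (1-D bounded maximisation)
        new_d = np.empty_like(dists)
        for idx, C in enumerate(counts):
            if not np.any(C - np.diag(np.diag(C))):
                new_d[idx] = 0.0
                continue
            res = minimize_scalar(
                lambda d: -_pair_loglik(d, q, pi, C),
                bounds=(1e-9, 20.0),
                method="bounded",
                options={"xatol": 1e-10},
            )
            new_d[idx] = res.x
        dists = new_d

        # shared rate-ratio update (2-D on log scale)
        from scipy.optimize import minimize

        res = minimize(
            lambda lk: -total_ll(np.exp(lk[0]), np.exp(lk[1]), dists),
            np.log(kappa),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10},
        )
        kappa = np.exp(res.x)

        new_ll = total_ll(kappa[0], kappa[1], dists)
        if not np.isfinite(new_ll):
            raise InestimableDistanceError("MCL: composite likelihood diverged")
        if abs(new_ll - ll) < tol:
            ll = new_ll
            break
        ll = new_ll
    else:
        raise InestimableDistanceError(
            f"MCL: no convergence after {max_iter} iterations (last ll={ll:.6g})"
        )

    d = np.zeros((n, n))
    for (i, j), v in zip(pairs, dists):
        d[i, j] = d[j, i] = max(float(v), 0.0)
    return DistanceMatrix(labels=seqs.labels, values=d, method="MCL")
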