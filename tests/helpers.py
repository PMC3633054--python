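"""Shared data and generators for the test suite."""

import numpy as np

from barcodecmp.simulate import HKYParams

BASES = np.array(list("ACGT"))

#: fixed 4-taxon, 300-bp alignment used for frozen reference-value tests
REF4 = {
    "t1": "TCTGATTTACCTGTCAGATGTCTTTACAAGTTCCCAACAGCTTCTTCAGAAATGTTCGAAGCGTGGGCACACTAAAAGGTGCTAAGTGAGAGCCCGCAATTGATTTCAATCACGATTTCGGAACACCAAGATGCAATCTACCTGCATGCATTAGAGGGTTATAAGCTTCTAGATAACTTTTTGCCGCATATAATAAGTACTTGAAAAGAGGGATTTAACCCCGTATCTGAACTGCTCTAATTAGGTGCCCGTCAATTAAGATCATAAAAAAAAGGCCGTTAAAAGCACGATATAATTTTG",
    "t2": "TCTGGTTTACCTGTCAGATATCTTTACAAGTTCCCAACAGCTCCTTAAGAAATGTTCGAAGCGTGGGTACACTAAAAGGTACCAAATTAGAGCCGGCAATTGATTTCAATTACGATTTCGGGATACCAAGACGCAATCTAACTACACGCATTAGAGAGCTATAAGATCCTAGATAACTTTTTGCTGCATATAAGAAATACTTGAAAAGATAATTTTAATCCCGTACAGGAACTGTTCTAAATAGCTGCCTGTCAATTAAGATCATAAAAAAAGGGCCGTTAAGAGCACGATGTATTTTTG",
    "t3": "TCCGGTTGACCTGTTGAATGCCTTTACAAGTTCCCAGCCACTTCTTCAGAAATGTTCGAAGCCTGGGCACACTGAAAGGTTCTAAGTCAGAGCCTGCATTCGATTTTAATCACGATTTCGGGTCACTAAGATGTGATCTACCTGAACGCATTAGAGGGTTGTAAGTTTCTAGATAACTTTTTGCTGCATATAATAAGTACATGAAAAGTGGGATTCAATTCCGTATAGGTTCCGTTCTAATTAGGTGCCTGTCAACCAAGATCATAAAAAAAAGGCCGTTAAAAGCATGATATGTTTTTG",
    "t4": "TCTGACTTACCTGTCAGATAACTTTGCAGATTCCCAACAATTTCTTCAGGAACGCTCGATACGTGGCTACGCTAAAAAGTGCTAGGTCAGAGCCCGCAATTGATTTCAATCGCAATTACGGGACATCAACATGTGCTCTACCTGTACGCATTAGGAAGTTATAAGCTGCTAGATTACTTTTCGTTACATATAACAAGTACTCGAAAGACGGTATCTAATTCCGTATAAGAGCCCTTCTGTTCAAGTGCCCGTTGACTAGGATCATAAAAAGAAGGCCTTTAAAAGCTCGACATATTTTTG",
}


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def evolve_from(rng: np.random.Generator, ancestor: str, distance: float) -> str:
    """Descendant of *ancestor* after *distance* substitutions/site of HKY."""
    hky = HKYParams.from_tstv(3.0, (0.3, 0.2, 0.2, 0.3))
    code = {b: i for i, b in enumerate("ACGT")}
    anc = np.array([code[b] for b in ancestor])
    p = hky.transition_matrix(distance)
    cum = np.cumsum(p, axis=1)
    u = rng.random(anc.size)
    der = np.empty(anc.size, dtype=np.int64)
    for s in range(4):
        mask = anc == s
        der[mask] = np.searchsorted(cum[s], u[mask], side="right")
    return "".join(BASES[der])


def hky_pair(rng: np.random.Generator, distance: float, length: int = 650):
    """An ancestral sequence and a descendant diverged by *distance*
    substitutions/site under the default HKY parameters."""
    hky = HKYParams.from_tstv(3.0, (0.3, 0.2, 0.2, 0.3))
    pi = np.asarray(hky.pi)
    anc = rng.choice(4, size=length, p=pi)
    p = hky.transition_matrix(distance)
    cum = np.cumsum(p, axis=1)
    u = rng.random(length)
    der = np.empty(length, dtype=np.int64)
    for s in range(4):
        mask = anc == s
        der[mask] = np.searchsorted(cum[s], u[mask], side="right")
    return "".join(BASES[anc]), "".join(BASES[der])
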