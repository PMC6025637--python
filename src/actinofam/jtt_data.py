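"""Jones-Taylor-Thornton (JTT) empirical amino-acid replacement model constants.

Exchangeabilities are the published integer-scaled lower-triangle values of
the JTT accepted-point-mutation matrix (Jones, Taylor & Thornton 1992), in
the conventional ARNDCQEGHILKMFPSTWYV residue order used by PAML and most
phylogenetics software.  The absolute scale of the exchangeabilities is
irrelevant: the rate matrix built from them is renormalised to one expected
substitution per site per unit time.
"""

import numpy as np

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

# Lower triangle, row-major: S[1,0], S[2,0], S[2,1], S[3,0], ...
_JTT_LOWER = [
    58,
    54, 45,
    81, 16, 528,
    56, 113, 34, 10,
    57, 310, 86, 49, 9,
    105, 29, 58, 767, 5, 323,
    179, 137, 81, 130, 59, 26, 119,
    27, 328, 391, 112, 69, 597, 26, 23,
    36, 22, 47, 11, 17, 9, 12, 6, 16,
    30, 38, 12, 7, 23, 72, 9, 6, 56, 229,
    35, 646, 263, 26, 7, 292, 181, 27, 45, 21, 14,
    54, 44, 30, 15, 31, 43, 18, 14, 33, 479, 388, 65,
    15, 5, 10, 4, 78, 4, 5, 5, 40, 89, 248, 4, 43,
    194, 74, 15, 15, 14, 164, 18, 24, 115, 10, 102, 21, 16, 17,
    378, 101, 503, 59, 223, 53, 30, 201, 73, 40, 59, 47, 29, 92, 285,
    475, 64, 232, 38, 42, 51, 32, 33, 46, 245, 25, 103, 226, 12, 118, 477,
    9, 126, 8, 4, 115, 18, 10, 55, 8, 9, 52, 10, 24, 53, 6, 35, 12,
    11, 20, 70, 46, 209, 24, 7, 8, 573, 32, 24, 8, 18, 536, 10, 63, 21, 71,
    298, 17, 16, 31, 62, 20, 45, 47, 11, 961, 180, 14, 323, 62, 23, 38, 112, 25, 16,
]

# Equilibrium amino-acid frequencies of the JTT model (jones.dat), same order.
_JTT_FREQS = [
    0.076748, 0.051691, 0.042645, 0.051544, 0.019803,
    0.040752, 0.061830, 0.073152, 0.022944, 0.053761,
    0.091904, 0.058676, 0.023826, 0.040126, 0.050901,
    0.068765, 0.058565, 0.014261, 0.032102, 0.066005,
]


def jtt_exchangeabilities() -> np.ndarray:
    """Return the symmetric 20x20 JTT exchangeability matrix (zero diagonal)."""
    s = np.zeros((20, 20))
    it = iter(_JTT_LOWER)
    for i in range(1, 20):
        for j in range(i):
            s[i, j] = s[j, i] = next(it)
    return s


def jtt_frequencies() -> np.ndarray:
    """Return JTT stationary frequencies normalised to sum exactly to 1."""
    pi = np.asarray(_JTT_FREQS, dtype=float)
    return pi / pi.sum()
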