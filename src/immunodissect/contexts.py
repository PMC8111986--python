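"""The 96 pyrimidine-centred trinucleotide substitution contexts and a
synthetic reference signature set.

Single-base substitutions are collapsed onto the pyrimidine strand, giving six
substitution types (C>A, C>G, C>T, T>A, T>C, T>G); with 4 x 4 flanking bases
this yields the canonical 96 mutation classes used for mutational-signature
analysis. Context codes are written ``A[C>T]G`` (5' flank, bracketed
substitution, 3' flank) and are ordered substitution-major, then 5' flank,
then 3' flank — the conventional catalogue ordering.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BASES = ("A", "C", "G", "T")
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: the 96 context codes in canonical order
CONTEXTS_96: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)

_CONTEXT_INDEX = {c: i for i, c in enumerate(CONTEXTS_96)}


def context_index(code: str) -> int:
    """Position of a context code in the canonical 96-vector ordering."""
    try:
        return _CONTEXT_INDEX[code]
    except KeyError:
        raise ValueError(f"not a canonical 96-context code: {code!r}") from None


def _peaked_profile(weights: dict[str, float], background: float) -> np.ndarray:
    """Column-stochastic 96-profile with mass concentrated on given contexts."""
    p = np.full(96, background, dtype=float)
    for code, w in weights.items():
        p[context_index(code)] += w
    return p / p.sum()


def synthetic_reference_signatures() -> pd.DataFrame:
    """A synthetic stand-in reference signature table (96 contexts x 5 signatures).

    These are parametric caricatures of well-known mutational processes, built
    in code rather than taken from any curated catalogue — adequate for
    exercising and validating signature extraction, not for interpreting real
    tumours:

    - ``apobec_tcw_cg`` / ``apobec_tcw_ct``: APOBEC-like C>G and C>T at TpCpA/T
      (the TCW motif), mimicking the two canonical APOBEC signatures.
    - ``aging_cpg_ct``: C>T at NpCpG, the clock-like deamination pattern.
    - ``smoking_ca``: broad C>A, the tobacco-associated pattern.
    - ``flat``: uniform background.
    """
    sigs = {
        "apobec_tcw_cg": _peaked_profile(
            {"T[C>G]A": 0.35, "T[C>G]T": 0.35}, background=0.003
        ),
        "apobec_tcw_ct": _peaked_profile(
            {"T[C>T]A": 0.30, "T[C>T]T": 0.30}, background=0.004
        ),
        "aging_cpg_ct": _peaked_profile(
            {f"{b}[C>T]G": 0.17 for b in BASES}, background=0.003
        ),
        "smoking_ca": _peaked_profile(
            {f"{b5}[C>A]{b3}": 0.05 for b5 in BASES for b3 in BASES},
            background=0.002,
        ),
        "flat": np.full(96, 1.0 / 96),
    }
    df = pd.DataFrame(sigs, index=pd.Index(CONTEXTS_96, name="context"))
    return df
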