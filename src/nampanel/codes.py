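"""Genotype code constants shared by every stage of the pipeline.

Genotypes are founder-origin symbols for within-population (GBS) markers and
allele symbols for dense projected SNPs: ``REF`` is the recurrent-parent
state (Col-0-like), ``ALT`` the alternate-parent state.  Codes are stored in
``int8`` matrices; ``MISSING`` is negative so boolean masks stay cheap.
"""

from __future__ import annotations

import numpy as np

REF: int = 0
ALT: int = 1
HET: int = 2
MISSING: int = -1

#: Origin of a genotype call: directly observed, filled by conservative
#: run imputation, or projected from the dense parental panel.
ORIGIN_OBSERVED: int = 0
ORIGIN_FILLED: int = 1
ORIGIN_PROJECTED: int = 2

VALID_CODES = frozenset({REF, ALT, HET, MISSING})

#: Letter codes used by the genotype CSV dialect.
CODE_TO_LETTER = {REF: "A", ALT: "B", HET: "H", MISSING: "-"}
LETTER_TO_CODE = {v: k for k, v in CODE_TO_LETTER.items()}


def is_homozygous(codes: np.ndarray) -> np.ndarray:
    """Boolean mask of homozygous (REF or ALT) calls."""
    return (codes == REF) | (codes == ALT)


def missing_fraction(codes: np.ndarray) -> float:
    """Fraction of MISSING calls in a code array."""
    if codes.size == 0:
        return 0.0
    return float(np.mean(codes == MISSING))
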