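"""The numeric motivation for semantic-invariant views.

Masking a subgraph of acetophenone's molecular graph can leave exactly the
graph of benzene — a different molecule.  Their octanol/water partition
coefficients, as tabulated in PubChem, differ substantially (acetophenone
LogP 1.58, benzene LogP 2.13), so treating the masked graph as a positive
pair of the original would align representations of molecules with clearly
different properties.  This module computes that headline gap.
"""

from __future__ import annotations

__all__ = ["ACETOPHENONE_LOGP", "BENZENE_LOGP", "relative_percent_difference",
           "masking_example_percent_difference"]

#: PubChem-tabulated experimental LogP values.
ACETOPHENONE_LOGP = 1.58
BENZENE_LOGP = 2.13


def relative_percent_difference(a: float, reference: float) -> float:
    """``100 * |a - reference| / |reference|``."""
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return 100.0 * abs(a - reference) / abs(reference)


def masking_example_percent_difference() -> float:
    """LogP gap between benzene and acetophenone, relative to acetophenone.

    Rounds to 35%: the property change caused by an apparently small
    structural edit.
    """
    return relative_percent_difference(BENZENE_LOGP, ACETOPHENONE_LOGP)
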