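"""RNA secondary-structure backend.

Thin wrapper around the ViennaRNA Python bindings.  Everything downstream
consumes only ``(structure, mfe)`` pairs in dot-bracket notation, so the
backend can be swapped (e.g. for an ``RNAfold`` subprocess) by replacing
:func:`fold`.
"""

from __future__ import annotations

import functools

try:
    import RNA as _vienna
except ImportError:  # pragma: no cover - environment without bindings
    _vienna = None


class FoldingBackendError(RuntimeError):
    """Raised when no RNA folding backend is available."""


@functools.lru_cache(maxsize=100_000)
def fold(seq: str) -> tuple[str, float]:
    """Fold an RNA sequence at 37 °C.

    Parameters
    ----------
    seq:
        RNA sequence (A/C/G/U, case-insensitive).

    Returns
    -------
    (structure, mfe):
        Dot-bracket minimum-free-energy structure and the MFE in kcal/mol
        (<= 0; exactly 0 for sequences that cannot pair).
    """
    if _vienna is None:
        raise FoldingBackendError(
            "ViennaRNA Python bindings are required for structure checks; "
            "install the 'ViennaRNA' package or configure an RNAfold-based "
            "backend."
        )
    structure, mfe = _vienna.fold(seq.upper().replace("T", "U"))
    return structure, float(mfe)


def paired_mask(structure: str) -> list[bool]:
    """Per-position flags: True where the dot-bracket structure pairs."""
    return [c != "." for c in structure]
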