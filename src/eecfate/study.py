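"""Published per-dataset cell counts of the enteroendocrine profiling study
this pipeline reproduces, used for bookkeeping arithmetic (stage sums,
population percentages).

Mouse small intestine (Neurog3-reporter SORT-seq): three developmental
stages pooled into one 1138-cell atlas.  Human: pluripotent-stem-cell-
derived intestinal organoids (HIO) and their transplanted, matured
counterparts (tHIO).
"""

from __future__ import annotations

MOUSE_STAGE_CELLS = {"E15.5": 384, "E18.5": 514, "P12": 240}
MOUSE_GENES_KEPT = 14_495

HIO_CELLS_PROFILED = 633
HIO_NEUROG3_POSITIVE = 156
HIO_HORMONE_CELLS = 414
HIO_GENES_KEPT = 16_513

THIO_CELLS_PROFILED = 560   # epithelial cells profiled (figure panel)
THIO_CELLS_QC_KEPT = 556    # reported after QC
THIO_EEC_CELLS = 461        # endocrine subset used for fate analysis
THIO_GENES_KEPT = 17_511


def mouse_total_cells() -> int:
    """Cells pooled across the three mouse stages."""
    return sum(MOUSE_STAGE_CELLS.values())


def hio_neurog3_percent() -> float:
    """Percent of profiled HIO cells expressing NEUROG3."""
    return 100.0 * HIO_NEUROG3_POSITIVE / HIO_CELLS_PROFILED


def hio_hormone_percent() -> float:
    """Percent of profiled HIO cells that are hormone-producing."""
    return 100.0 * HIO_HORMONE_CELLS / HIO_CELLS_PROFILED


def thio_eec_percent() -> float:
    """Percent of profiled tHIO epithelial cells in the endocrine subset."""
    return 100.0 * THIO_EEC_CELLS / THIO_CELLS_PROFILED
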