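"""Figure export: the complexity resonance diagram.

Rows are items, columns are window-anchor days, cell colour encodes dynamic
complexity (dark = low, warm = high).  Undefined cells (windows contaminated
by missing data) are rendered in a visually distinct grey.  Detected
instability phases and the ERP onset can be overlaid as horizontal/vertical
markers.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .complexity import ComplexityMatrix

__all__ = ["render_resonance_diagram"]


def render_resonance_diagram(
    matrix: ComplexityMatrix,
    path: str | Path,
    phases: list[tuple[int, int]] | None = None,
    erp_onset: int | None = None,
) -> Path:
    """Write a heat-map image of the complexity matrix; returns the path."""
    if matrix.C.size == 0:
        raise ValueError("cannot render an empty complexity matrix")
    fig, ax = plt.subplots(
        figsize=(max(6.0, matrix.days.size * 0.12), max(2.5, len(matrix.item_ids) * 0.18))
    )
    cmap = plt.get_cmap("inferno").copy()
    cmap.set_bad("0.7")
    data = np.ma.masked_invalid(matrix.C)
    extent = (
        matrix.days[0] - 0.5,
        matrix.days[-1] + 0.5,
        len(matrix.item_ids) - 0.5,
        -0.5,
    )
    im = ax.imshow(data, aspect="auto", cmap=cmap, vmin=0.0, extent=extent,
                   interpolation="nearest")
    ax.set_xlabel("window anchor day")
    ax.set_ylabel("item")
    if len(matrix.item_ids) <= 20:
        ax.set_yticks(range(len(matrix.item_ids)), matrix.item_ids, fontsize=6)
    else:
        ax.set_yticks([])
    ax.set_title(f"Complexity resonance diagram — {matrix.patient_id}")
    fig.colorbar(im, ax=ax, label="dynamic complexity C")
    if phases:
        for start, end in phases:
            ax.axvspan(start - 0.5, end + 0.5, color="tab:brown", alpha=0.25, lw=0)
    if erp_onset is not None:
        ax.axvline(erp_onset, color="tab:green", lw=2, label="ERP onset")
        ax.legend(loc="upper right", fontsize=7)
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path
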