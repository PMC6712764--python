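"""Post-processing: voxel classifications, planar sections, sweep reports.

The occupancy color code summarizes tumor architecture per voxel: voxels the
tumor has reached (nonzero live + necrotic tumor cells) are *cyan* while the
total occupying population (live tumor + all necrotic) stays at or below 50%
of the average capacity M, and otherwise *blue*, *gray* or *black* as the
total necrotic population (tumor + host) passes 65% and 95% of M — the
gray-to-black gradient is the necrotic core.  Voxels holding only necrotic
host cells (or nothing) are *untouched* and not rendered.

Chemical fields and vascular capacity are rendered as shades of the ratio to
their normal-tissue level; the capacity code additionally distinguishes
angiogenesis-expanded voxels (ratios above 100%).  Threshold edges are
left-closed: a ratio exactly at a bin edge falls in the upper bin.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "OCCUPANCY_CLASSES",
    "classify_occupancy",
    "classify_field",
    "CHEMICAL_BINS",
    "CAPACITY_BINS",
    "extract_section",
    "sweep_report",
    "render_section",
    "plot_trajectories",
]

OCCUPANCY_CLASSES = ("untouched", "cyan", "blue", "gray", "black")

#: Ratio bin edges for chemical stocks (x / x_normal).  The extreme classes
#: are "below 15% of normal" (darkest) and "at least normal" (lightest).
CHEMICAL_BINS = (0.15, 0.30, 0.50, 0.75, 1.0)

#: Ratio bin edges for vascular capacity: regressed below normal, normal,
#: and the 100-125% / 125-150% / >150% angiogenic classes.
CAPACITY_BINS = (0.50, 1.0, 1.25, 1.50)


def classify_occupancy(
    l: np.ndarray, nc: np.ndarray, nn: np.ndarray, M: float
) -> np.ndarray:
    """Per-voxel occupancy class (strings from :data:`OCCUPANCY_CLASSES`)."""
    l, nc, nn = (np.asarray(a, dtype=float) for a in (l, nc, nn))
    reached = (l + nc) > 0
    total = l + nc + nn
    necrotic = nc + nn
    out = np.full(l.shape, "untouched", dtype="U9")
    out[reached & (total <= 0.5 * M)] = "cyan"
    heavy = reached & (total > 0.5 * M)
    out[heavy & (necrotic < 0.65 * M)] = "blue"
    out[heavy & (necrotic >= 0.65 * M) & (necrotic < 0.95 * M)] = "gray"
    out[heavy & (necrotic >= 0.95 * M)] = "black"
    return out


def classify_field(
    x: np.ndarray, x_normal: float, bins: tuple = CHEMICAL_BINS
) -> np.ndarray:
    """Bin the ratio ``x / x_normal`` into shade classes (0 = darkest).

    Left-closed bins: class ``i`` covers ``bins[i-1] <= ratio < bins[i]``;
    class ``len(bins)`` is ``ratio >= bins[-1]``.
    """
    if x_normal <= 0:
        raise ValueError("x_normal must be positive")
    ratio = np.asarray(x, dtype=float) / x_normal
    return np.digitize(ratio, bins, right=False)


def extract_section(vec: np.ndarray, axis: str, index: int, N: int) -> np.ndarray:
    """Extract the N x N plane ``axis = index`` (1-based) from an L-order
    vector.

    The returned array keeps L-consistent orientation: rows run along the
    slower and columns along the faster of the two remaining coordinates.
    """
    if axis not in ("i", "j", "k"):
        raise ValueError("axis must be one of 'i', 'j', 'k'")
    if not 1 <= index <= N:
        raise ValueError(f"plane index {index} outside 1..{N}")
    cube = np.asarray(vec).reshape(N, N, N)  # cube[k, j, i]
    if axis == "i":
        return cube[:, :, index - 1]  # (k, j)
    if axis == "j":
        return cube[:, index - 1, :]  # (k, i)
    return cube[index - 1, :, :]  # (j, i)


def sweep_report(
    cells: list[dict],
    out_csv: str | Path | None = None,
    out_png: str | Path | None = None,
) -> pd.DataFrame:
    """Tabulate an ensemble sweep and optionally render the 'skewed bars'.

    ``cells`` is a list of ``{"label": ..., "summary": EnsembleSummary}``
    plus any extra parameter columns; the report carries, per sweep cell, the
    survival probability, the conditional mean of the final live population
    over surviving replicates, and the sorted-descending final counts.
    """
    rows = []
    for cell in cells:
        s = cell["summary"]
        extra = {k: v for k, v in cell.items() if k != "summary"}
        rows.append(
            {
                **extra,
                "n_replicates": len(s.final_live),
                "survival_probability": s.survival_probability,
                "conditional_mean_live": s.conditional_mean_live,
                "sorted_final_live": ";".join(
                    f"{v:.6g}" for v in s.sorted_final_live
                ),
            }
        )
    df = pd.DataFrame(rows)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    if out_png is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 0.6 * len(cells) + 1.5))
        for row_i, cell in enumerate(cells):
            vals = cell["summary"].sorted_final_live
            n = len(vals)
            top = len(cells) - row_i
            vmax = max(vals.max(), 1.0)
            for k, v in enumerate(vals):
                y = top - (k + 0.5) / n
                ax.plot([0, v / vmax], [y, y], color="C0", lw=0.8)
            ax.text(1.02, top - 0.5, str(cell.get("label", row_i)), fontsize=7,
                    va="center")
        ax.set_xlim(0, 1.15)
        ax.set_ylim(0, len(cells))
        ax.set_yticks([])
        ax.set_xlabel("final live cancer cells (per-row relative scale)")
        fig.tight_layout()
        fig.savefig(out_png, dpi=150)
        plt.close(fig)
    return df


def render_section(
    class_array: np.ndarray,
    out_png: str | Path | None = None,
    out_csv: str | Path | None = None,
    cmap: str = "viridis",
) -> None:
    """Write a 2-D class array as a raster PNG and/or a CSV table."""
    if out_csv is not None:
        pd.DataFrame(class_array).to_csv(out_csv, index=False, header=False)
    if out_png is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        codes = class_array
        if codes.dtype.kind in "US":
            lut = {name: i for i, name in enumerate(OCCUPANCY_CLASSES)}
            codes = np.vectorize(lut.get)(class_array)
        fig, ax = plt.subplots()
        im = ax.imshow(codes, origin="lower", cmap=cmap, interpolation="nearest")
        fig.colorbar(im, ax=ax)
        fig.savefig(out_png, dpi=150)
        plt.close(fig)


def plot_trajectories(
    per_day: pd.DataFrame,
    out_png: str | Path,
    label: str = "",
    column: str = "total_live",
) -> None:
    """Overlay per-replicate daily trajectories of ``column`` (mean in bold)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    for _, grp in per_day.groupby("replicate"):
        ax.plot(grp["t_days"], grp[column], color="C0", alpha=0.3, lw=0.8)
    mean = per_day.groupby("t_days")[column].mean()
    ax.plot(mean.index, mean.values, color="C3", lw=2, label=f"mean {label}")
    ax.set_xlabel("time (days)")
    ax.set_ylabel(column)
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_png, dpi=150)
    plt.close(fig)
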