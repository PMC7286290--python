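"""Quick-look exports: phase-colored projections and phenotype heatmaps."""

from __future__ import annotations

import numpy as np

#: display colors per phase (the usual light-sheet screen convention)
PHASE_COLORS = {
    "interphase": (1.0, 1.0, 1.0),
    "prophase": (0.0, 0.9, 0.2),
    "metaphase": (1.0, 0.9, 0.0),
    "anaphase": (1.0, 0.15, 0.15),
    "macronuclei": (0.4, 0.6, 1.0),
    "apoptotic_condensed_DNA": (0.8, 0.3, 1.0),
}


def save_projection_png(volume, records, path, voxel_size=None, dpi=120):
    """Maximum-intensity Z projection with class-colored nucleus markers.

    ``records`` are NucleusRecords with centroids in µm and (optionally)
    phase calls; unclassified nuclei are drawn grey.  Intended for visual
    QC of a time lapse, one PNG per frame.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = np.asarray(volume.data, dtype=float)
    v = voxel_size or getattr(volume, "voxel_size", 1.0)
    if isinstance(v, tuple):
        v = v[0]
    proj = data.max(axis=0)
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(proj, cmap="gray", origin="lower",
              extent=(0, proj.shape[1] * v, 0, proj.shape[0] * v))
    for r in records:
        color = PHASE_COLORS.get(r.phase, (0.6, 0.6, 0.6))
        ax.plot(r.centroid[0], r.centroid[1], "o", mfc="none",
                mec=color, ms=9, mew=1.5)
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.set_title(f"t = {records[0].timepoint}" if records else "projection")
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)


def save_heatmap_png(matrix, path, assignments=None, dpi=120):
    """Heatmap of a scaled phenotype matrix (samples × features).

    Rows are ordered by cluster assignment when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = matrix.data if hasattr(matrix, "data") else matrix
    if assignments is not None:
        df = df.loc[assignments.sort_values().index]
    fig, ax = plt.subplots(figsize=(max(4, 0.3 * df.shape[1]),
                                    max(3, 0.25 * df.shape[0])))
    im = ax.imshow(df.to_numpy(dtype=float), aspect="auto", cmap="RdBu_r",
                   vmin=-3, vmax=3)
    ax.set_xticks(range(df.shape[1]))
    ax.set_xticklabels(df.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(df.shape[0]))
    ax.set_yticklabels(df.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="z-score")
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
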