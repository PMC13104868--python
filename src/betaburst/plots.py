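"""Plain summary figures for a completed run directory.

Deliberately unstyled: one scatter of burst vs non-burst coupling, one
observed-vs-surrogate scatter, and the p-value ECDFs per metric.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .surrogates import null_ecdf  # noqa: E402


def figures(run_dir) -> list[str]:
    """Write summary figures next to the run's tables; returns the paths."""
    run_dir = Path(run_dir)
    pairs = pd.read_csv(run_dir / "pair_coupling.tsv", sep="\t")
    written = []

    fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
    for ax, metric in zip(axes, ("coh", "dwpli")):
        ax.scatter(pairs[f"{metric}_nonburst"], pairs[f"{metric}_burst"], s=12)
        lim = max(ax.get_xlim()[1], ax.get_ylim()[1])
        ax.plot([0, lim], [0, lim], "k--", lw=0.8)
        ax.set_xlabel(f"non-burst {metric}")
        ax.set_ylabel(f"burst {metric}")
    fig.tight_layout()
    path = run_dir / "burst_vs_nonburst.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(str(path))

    fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
    grid = np.linspace(0, 1, 201)
    for ax, metric in zip(axes, ("coh", "dwpli")):
        for cond in ("burst", "nonburst"):
            col = f"p_{metric}_{cond}"
            if col in pairs and len(pairs):
                ax.step(grid, null_ecdf(pairs[col].to_numpy())(grid),
                        where="post", label=cond)
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel(f"{metric} surrogate p")
        ax.set_ylabel("ECDF")
        ax.legend(frameon=False)
    fig.tight_layout()
    path = run_dir / "p_value_ecdfs.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(str(path))

    fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
    for ax, metric in zip(axes, ("coh", "dwpli")):
        obs = pairs[f"{metric}_nonburst"]
        sur = pairs.get(f"null_mean_{metric}_nonburst")
        if sur is not None:
            ax.scatter(sur, obs, s=12)
            lim = max(ax.get_xlim()[1], ax.get_ylim()[1])
            ax.plot([0, lim], [0, lim], "k--", lw=0.8)
        ax.set_xlabel(f"surrogate mean non-burst {metric}")
        ax.set_ylabel(f"observed non-burst {metric}")
    fig.tight_layout()
    path = run_dir / "observed_vs_surrogate.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(str(path))
    return written
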