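"""Paired statistics, effect sizes, correlations and contact summaries.

Burst vs non-burst coupling contrasts are reported as two-sided Wilcoxon
signed-rank tests (exact for n <= 25, normal approximation with tie
correction above), paired t-tests for completeness, and the paired effect
size d_z = mean(diff) / sd(diff) with the sample (n-1) standard deviation.
Note the field also writes this quantity as paired Cohen's d; outputs here
label it ``cohens_dz`` to make the difference-standardized variant explicit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats

WILCOXON_EXACT_MAX_N = 25


@dataclass
class PairedResult:
    n: int
    wilcoxon_p: float
    ttest_p: float
    cohens_dz: float
    mean_diff: float
    degenerate: bool = False  # all differences zero: tests undefined


@dataclass
class ContactSummary:
    cortical_contact: str
    n_pairs: int
    frac_nonburst_exceeding: float
    frac_burst_exceeding: float
    frac_none: float
    mean_coh_burst: float
    mean_coh_nonburst: float
    mean_dwpli_burst: float
    mean_dwpli_nonburst: float


def paired_compare(a: np.ndarray, b: np.ndarray) -> PairedResult:
    """Two-sided paired comparison of two per-pair value vectors.

    Zero differences are dropped for the Wilcoxon test (signed-rank
    convention); if every difference is zero the tests are undefined and
    the result is flagged degenerate with d_z = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    if np.all(d == 0) or sd == 0:
        return PairedResult(
            n=n, wilcoxon_p=np.nan, ttest_p=np.nan, cohens_dz=0.0,
            mean_diff=mean_diff, degenerate=True,
        )
    method = "exact" if np.count_nonzero(d) <= WILCOXON_EXACT_MAX_N else "approx"
    wres = spstats.wilcoxon(d, zero_method="wilcox", correction=False,
                            alternative="two-sided", method=method)
    tres = spstats.ttest_rel(a, b)
    return PairedResult(
        n=n,
        wilcoxon_p=float(wres.pvalue),
        ttest_p=float(tres.pvalue),
        cohens_dz=mean_diff / sd,
        mean_diff=mean_diff,
    )


def spearman_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation (average-rank ties, two-sided t-based p).

    Constant input leaves the correlation undefined; returns (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho, p = spstats.spearmanr(x, y)
    return float(rho), float(p)


def contact_summary(pair_table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-cortical-contact fractions of pairs exceeding surrogate nulls.

    Expects one row per STN-cortical pair with columns ``ctx_label``,
    ``coh_burst``, ``coh_nonburst``, ``dwpli_burst``, ``dwpli_nonburst``
    and surrogate p-value columns ``p_coh_burst``, ``p_coh_nonburst``,
    ``p_dwpli_burst``, ``p_dwpli_nonburst``.  ``frac_none`` counts pairs
    for which neither condition is significant (coherence metric).
    """
    required = {
        "ctx_label", "coh_burst", "coh_nonburst", "dwpli_burst", "dwpli_nonburst",
        "p_coh_burst", "p_coh_nonburst", "p_dwpli_burst", "p_dwpli_nonburst",
    }
    missing = required - set(pair_table.columns)
    if missing:
        raise ValueError(f"pair table is missing columns: {sorted(missing)}")
    rows = []
    for ctx, g in pair_table.groupby("ctx_label", sort=True):
        sig_b = g["p_coh_burst"] < alpha
        sig_nb = g["p_coh_nonburst"] < alpha
        rows.append(
            {
                "cortical_contact": ctx,
                "n_pairs": len(g),
                "frac_burst_exceeding": float(sig_b.mean()),
                "frac_nonburst_exceeding": float(sig_nb.mean()),
                "frac_none": float((~sig_b & ~sig_nb).mean()),
                "frac_burst_exceeding_dwpli": float((g["p_dwpli_burst"] < alpha).mean()),
                "frac_nonburst_exceeding_dwpli": float((g["p_dwpli_nonburst"] < alpha).mean()),
                "mean_coh_burst": float(g["coh_burst"].mean()),
                "mean_coh_nonburst": float(g["coh_nonburst"].mean()),
                "mean_dwpli_burst": float(g["dwpli_burst"].mean()),
                "mean_dwpli_nonburst": float(g["dwpli_nonburst"].mean()),
            }
        )
    return pd.DataFrame(rows)


def _fmt_p(p: float, n_surrogates: int | None = None) -> str:
    if np.isnan(p):
        return "undefined"
    if p == 0 and n_surrogates:
        return f"< {1.0 / n_surrogates:.3g}"
    return f"{p:.3g}"


def paired_block(name: str, res: PairedResult) -> list[str]:
    lines = [f"### {name}", ""]
    if res.degenerate:
        lines.append(f"- n = {res.n}: all differences zero; tests undefined")
    else:
        lines += [
            f"- n = {res.n} pairs",
            f"- mean difference = {res.mean_diff:.4g}",
            f"- Wilcoxon signed-rank p = {_fmt_p(res.wilcoxon_p)}"
            f", paired t-test p = {_fmt_p(res.ttest_p)}",
            f"- paired effect size d_z = {res.cohens_dz:.3g}",
        ]
        if not np.isnan(res.wilcoxon_p) and res.wilcoxon_p < 0.05 and abs(res.cohens_dz) < 0.3:
            lines.append(
                "- note: statistically significant but small effect "
                f"(|d_z| = {abs(res.cohens_dz):.2g}); interpret the magnitude, not the p-value"
            )
    lines.append("")
    return lines


def report(run_dir) -> str:
    """Render the Markdown summary for a completed pipeline run.

    Requires the stage outputs written by the pipeline; a missing stage is
    reported by name.  Returns the path of the written report.
    """
    from pathlib import Path

    run_dir = Path(run_dir)
    needed = {
        "pair coupling + surrogate stage": run_dir / "pair_coupling.tsv",
        "burst-adjacent stage": run_dir / "adjacent_coupling.tsv",
        "epoch detection stage": run_dir / "epoch_counts.tsv",
    }
    for stage, path in needed.items():
        if not path.exists():
            raise FileNotFoundError(f"missing output of {stage}: {path}")
    pairs = pd.read_csv(needed["pair coupling + surrogate stage"], sep="\t")
    adjacent = pd.read_csv(needed["burst-adjacent stage"], sep="\t")
    counts = pd.read_csv(needed["epoch detection stage"], sep="\t")

    lines = ["# Burst-resolved cortico-STN beta coupling report", ""]

    lines += ["## Epoch detection", ""]
    lines.append(counts.to_markdown(index=False))
    lines.append("")

    lines += ["## Burst vs non-burst coupling", ""]
    if len(pairs) >= 2:
        lines += paired_block(
            "Coherence", paired_compare(pairs["coh_burst"].values, pairs["coh_nonburst"].values)
        )
        lines += paired_block(
            "dwPLI", paired_compare(pairs["dwpli_burst"].values, pairs["dwpli_nonburst"].values)
        )
    else:
        lines.append("- too few pairs for paired statistics")
        lines.append("")

    lines += ["## Surrogate testing", ""]
    for metric in ("coh", "dwpli"):
        for cond in ("burst", "nonburst"):
            col = f"p_{metric}_{cond}"
            if col in pairs:
                frac = float((pairs[col] < 0.05).mean())
                lines.append(
                    f"- {metric} {cond}: {frac:.0%} of pairs exceed the surrogate null "
                    f"(p < 0.05), median p = {pairs[col].median():.3g}"
                )
    if len(pairs) >= 3:
        for metric in ("coh", "dwpli"):
            obs = pairs[f"{metric}_nonburst"].values
            sur = pairs[f"null_mean_{metric}_nonburst"].values
            rho, p = spearman_corr(obs, sur)
            lines.append(
                f"- observed vs surrogate-mean non-burst {metric}: Spearman rho = {rho:.3g} "
                f"(p = {_fmt_p(p)})"
            )
    lines.append("")

    lines += ["## Contact summary", ""]
    lines.append(contact_summary(pairs).to_markdown(index=False))
    lines.append("")

    lines += ["## Burst-adjacent coupling", ""]
    if len(adjacent) >= 2:
        for metric in ("coh", "dwpli"):
            lines += paired_block(
                f"{metric}: burst vs pre",
                paired_compare(adjacent[f"{metric}_burst"].values, adjacent[f"{metric}_pre"].values),
            )
            lines += paired_block(
                f"{metric}: burst vs post",
                paired_compare(adjacent[f"{metric}_burst"].values, adjacent[f"{metric}_post"].values),
            )
            lines += paired_block(
                f"{metric}: pre vs post",
                paired_compare(adjacent[f"{metric}_pre"].values, adjacent[f"{metric}_post"].values),
            )
    elif len(adjacent) == 1:
        row = adjacent.iloc[0]
        for metric in ("coh", "dwpli"):
            lines.append(
                f"- {metric}: burst {row[f'{metric}_burst']:.3g}, "
                f"pre {row[f'{metric}_pre']:.3g}, post {row[f'{metric}_post']:.3g} "
                f"({int(row['n_valid_triplets'])} valid triplets; "
                "single pair, no paired statistics)"
            )
        lines.append("")
    else:
        lines.append("- no contact pairs with enough valid triplets")
        lines.append("")

    out = run_dir / "report.md"
    out.write_text("\n".join(lines))
    return str(out)
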