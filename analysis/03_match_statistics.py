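"""Per-patient match-fraction statistics and dot plots.

Reads the per-patient fractions written by 02_trace_igg.py, reports the
median and range of the overall matched fraction, the per-cell-type and
expanded-vs-singleton comparisons with exact two-tailed Wilcoxon
signed-rank p-values, and draws per-patient dot plots under
results/figures/.
"""

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

ROOT = Path(__file__).resolve().parent.parent / "results"
RUN = ROOT / "run"
FIGDIR = ROOT / "figures"


def dot_plot(ax, fractions: pd.DataFrame, strata: list[str], title: str) -> None:
    for i, name in enumerate(strata):
        vals = fractions[f"{name}_fraction"]
        vals = pd.to_numeric(vals, errors="coerce").dropna()
        ax.scatter([i] * len(vals), vals, alpha=0.7)
        ax.hlines(vals.median(), i - 0.2, i + 0.2, color="black")
    ax.set_xticks(range(len(strata)), strata)
    ax.set_ylabel("fraction of collapsed units matched")
    ax.set_title(title)
    ax.set_ylim(-0.02, 1.0)


def main() -> None:
    fractions = pd.read_csv(RUN / "fractions.tsv", sep="\t")
    summary = json.loads((RUN / "summary.json").read_text())

    med = summary["overall_matched_fraction_median"]
    lo, hi = summary["overall_matched_fraction_range"]
    print(
        f"overall: median {100 * med:.1f}% (range {100 * lo:.1f}-{100 * hi:.1f}%) "
        "of collapsed B-lineage units matched intrathecally produced IgG"
    )
    for name, c in summary["comparisons"].items():
        if c["p_two_sided"] is None:
            print(f"{name}: {c['message']}")
        else:
            print(
                f"{name}: medians {c['median_a']:.3f} vs {c['median_b']:.3f}, "
                f"W={c['W']:.1f}, exact two-tailed p={c['p_two_sided']:.4g} "
                f"(n={c['n_pairs']} patients)"
            )

    FIGDIR.mkdir(parents=True, exist_ok=True)
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    dot_plot(axes[0], fractions, ["ASC", "memory", "naive"], "by cell type")
    dot_plot(axes[1], fractions, ["expanded", "singleton"], "by expansion")
    fig.tight_layout()
    fig.savefig(FIGDIR / "match_fractions.png", dpi=150)
    print(f"wrote {FIGDIR / 'match_fractions.png'}")


if __name__ == "__main__":
    main()
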