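#!/usr/bin/env python
"""Plot a bifurcation-diagram TSV produced by `vegroots scan-bifurcation`.

Usage: python scripts/plot_bifurcation.py diagram.tsv out.png
"""

import sys

import pandas as pd


def main() -> int:
    if len(sys.argv) != 3:
        print(__doc__)
        return 2
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = pd.read_csv(sys.argv[1], sep="\t")
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharex=True)
    colors = {"BS": "tab:brown", "GU": "tab:green", "CU": "tab:olive",
              "MU": "tab:purple"}
    for (branch, stable), part in df.groupby(
            ["branch", df.stable_uniform & df.stable_nonuniform]):
        style = "-" if stable else "--"
        for ax, col in zip(axes, ("B1", "B2")):
            ax.plot(part.P, part[col], style, color=colors.get(branch, "k"),
                    label=f"{branch} ({'stable' if stable else 'unstable'})")
    for ax, col in zip(axes, ("B1", "B2")):
        ax.set_xlabel("P [mm/y]")
        ax.set_ylabel(f"{col} [kg/m$^2$]")
    handles, labels = axes[0].get_legend_handles_labels()
    seen = dict(zip(labels, handles))
    axes[1].legend(seen.values(), seen.keys(), fontsize=8)
    fig.tight_layout()
    fig.savefig(sys.argv[2], dpi=150)
    print(f"wrote {sys.argv[2]}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
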