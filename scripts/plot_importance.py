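#!/usr/bin/env python
"""Render an importance matrix CSV (from ``medbias importance``) as a heatmap.

Convenience only — no test depends on this output.

Usage::

    python scripts/plot_importance.py matrix.csv heatmap.png
"""

import sys

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from medbias.importance import read_importance


def main() -> None:
    if len(sys.argv) != 3:
        sys.exit(__doc__)
    matrix = read_importance(sys.argv[1])
    fig, ax = plt.subplots(figsize=(4 + 0.6 * matrix.values.shape[1], 0.3 * len(matrix.words) + 2))
    im = ax.imshow(matrix.values.to_numpy(), cmap="RdBu_r", vmin=-2, vmax=2, aspect="auto")
    ax.set_xticks(range(matrix.values.shape[1]), matrix.values.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(matrix.words)), matrix.words)
    fig.colorbar(im, ax=ax, label="mean effect size")
    fig.tight_layout()
    fig.savefig(sys.argv[2], dpi=150)
    print(f"wrote {sys.argv[2]}")


if __name__ == "__main__":
    main()
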