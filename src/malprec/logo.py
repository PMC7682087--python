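"""Two-sample positional residue-enrichment analysis.

Compares aligned positive and negative window sets position by position:
for every non-center offset and each of the 20 amino acids, the
per-window presence indicator (1 if the residue occupies that position)
is compared between the two sets with a two-sample t-test (pooled
variance by default, the classic two-sample-logo convention; Welch
available).  Enrichment direction comes from the sign of the frequency
difference.  The padding residue X and the invariant center lysine are
not tested.

No multiple-testing correction is applied by default (raw p < alpha);
Bonferroni-adjusted significance can be reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .windows import AA20, PeptideWindow

ENRICHED = "enriched-in-positive"
DEPLETED = "depleted-in-positive"
EQUAL = "equal"


@dataclass
class EnrichmentTable:
    """Per-(position, residue) t-test results as a tidy DataFrame.

    Columns: ``position`` (signed offset from the center, 0 excluded),
    ``residue``, ``pos_freq``, ``neg_freq``, ``t_statistic``,
    ``p_value``, ``direction``, ``significant`` and (when requested)
    ``significant_bonferroni``.
    """

    table: pd.DataFrame
    alpha: float
    n_pos: int
    n_neg: int

    def significant_cells(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _indicators(windows: Sequence[PeptideWindow | str], length: int) -> np.ndarray:
    """(n_windows, length) array of residue characters."""
    rows = []
    for w in windows:
        s = w.residues if isinstance(w, PeptideWindow) else w
        if len(s) != length:
            raise ValueError(f"window length {len(s)} != expected {length}")
        rows.append(list(s))
    return np.array(rows)


def _ttest_binary(a: np.ndarray, b: np.ndarray, welch: bool) -> tuple[float, float]:
    """Two-sample t-test on binary indicator vectors, degenerate-safe."""
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.inf) * np.sign(a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def positional_enrichment(
    pos_windows: Sequence[PeptideWindow | str],
    neg_windows: Sequence[PeptideWindow | str],
    alpha: float = 0.05,
    n: int | None = None,
    welch: bool = False,
    bonferroni: bool = False,
) -> EnrichmentTable:
    """Per-cell enrichment of positives vs negatives.

    ``n`` is the upstream flank length used to locate the center (taken
    from the first window if it is a :class:`PeptideWindow`, else
    assumed symmetric).  Offsets run -n..-1 and +1..+(L-n-1).
    """
    if not len(pos_windows) or not len(neg_windows):
        raise ValueError("both window sets must be non-empty")
    first = pos_windows[0]
    length = len(first.residues) if isinstance(first, PeptideWindow) else len(first)
    if n is None:
        n = first.n if isinstance(first, PeptideWindow) else (length - 1) // 2
    P = _indicators(pos_windows, length)
    N = _indicators(neg_windows, length)

    rows = []
    for col in range(length):
        if col == n:
            continue  # invariant center lysine
        offset = col - n
        pc = P[:, col]
        nc = N[:, col]
        for res in AA20:
            a = (pc == res).astype(float)
            b = (nc == res).astype(float)
            t, p = _ttest_binary(a, b, welch)
            diff = a.mean() - b.mean()
            direction = ENRICHED if diff > 0 else DEPLETED if diff < 0 else EQUAL
            rows.append({
                "position": offset,
                "residue": res,
                "pos_freq": a.mean(),
                "neg_freq": b.mean(),
                "t_statistic": t,
                "p_value": p,
                "direction": direction,
                "significant": bool(p < alpha),
            })
    df = pd.DataFrame(rows)
    if bonferroni:
        df["significant_bonferroni"] = df["p_value"] < alpha / len(df)
    return EnrichmentTable(table=df, alpha=alpha, n_pos=len(pos_windows),
                           n_neg=len(neg_windows))


def plot_enrichment(table: EnrichmentTable, path) -> None:
    """Frequency-difference logo: enriched residues stack up, depleted down.

    Only cells significant at the configured alpha are drawn; letter
    height is the absolute positive-negative frequency difference.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = table.significant_cells()
    positions = sorted(table.table["position"].unique())
    fig, ax = plt.subplots(figsize=(max(6, len(positions) * 0.6), 4))
    for pos in positions:
        cells = df[df["position"] == pos]
        up = cells[cells["direction"] == ENRICHED].sort_values("pos_freq")
        down = cells[cells["direction"] == DEPLETED].sort_values("neg_freq")
        y = 0.0
        for _, row in up.iterrows():
            h = row["pos_freq"] - row["neg_freq"]
            ax.text(pos, y + h / 2, row["residue"], ha="center", va="center",
                    fontsize=8 + 40 * h, color="tab:green")
            y += h
        y = 0.0
        for _, row in down.iterrows():
            h = row["neg_freq"] - row["pos_freq"]
            ax.text(pos, -(y + h / 2), row["residue"], ha="center", va="center",
                    fontsize=8 + 40 * h, color="tab:red")
            y += h
    lim = max(0.05, (df["pos_freq"] - df["neg_freq"]).abs().max() * 2.0) if len(df) else 0.1
    ax.set_xlim(min(positions) - 1, max(positions) + 1)
    ax.set_ylim(-lim, lim)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("offset from center lysine")
    ax.set_ylabel("frequency difference (pos - neg)")
    ax.set_title(f"enriched (up) / depleted (down), p < {table.alpha}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
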