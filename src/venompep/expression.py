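"""Category-level expression percentages from per-contig read counts.

Raw mapped-read proportions are used without transcript-length (RPKM)
normalization: the abundant venom-peptide transcripts are short, and for a
relative profile of a single library the raw read share is the quantity of
interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["ExpressionProfile", "profile", "plot_profile"]

REQUIRED_COLUMNS = ("contig", "group", "category", "count")
VALID_GROUPS = ("toxin", "non_toxin", "unidentified")


@dataclass(frozen=True)
class ExpressionProfile:
    """Two-level expression breakdown, in percent of mapped reads.

    ``top`` covers toxin / non-toxin / unidentified shares of all reads;
    ``within_toxin`` covers per-family shares of the toxin reads only.
    Both levels sum to 100 (to numerical precision) over the groups present.
    """

    top: pd.Series
    within_toxin: pd.Series

    def rounded(self, decimals: int = 1) -> "ExpressionProfile":
        return ExpressionProfile(
            self.top.round(decimals), self.within_toxin.round(decimals)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [("all_reads", grp, pct) for grp, pct in self.top.items()]
        rows += [("toxin_reads", fam, pct) for fam, pct in self.within_toxin.items()]
        return pd.DataFrame(rows, columns=["level", "category", "percent"])


def profile(table: pd.DataFrame) -> ExpressionProfile:
    """Aggregate a count table into two-level expression percentages.

    ``table`` needs columns ``contig`` (unique ids), ``group`` (one of
    ``toxin``/``non_toxin``/``unidentified``), ``category`` (family name
    within the group) and ``count`` (non-negative integer mapped reads).
    Percentages are invariant under uniform scaling of all counts.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"count table is missing column(s): {missing}")
    if table["contig"].duplicated().any():
        dup = table.loc[table["contig"].duplicated(), "contig"].iloc[0]
        raise ValueError(f"duplicate contig id {dup!r}")
    counts = table["count"]
    if (counts < 0).any() or (counts != counts.astype(int)).any():
        raise ValueError("counts must be non-negative integers")
    bad_groups = set(table["group"]) - set(VALID_GROUPS)
    if bad_groups:
        raise ValueError(
            f"unknown group(s) {sorted(bad_groups)}; expected one of {VALID_GROUPS}"
        )
    total = counts.sum()
    if total == 0:
        raise ValueError("total read count is zero")

    top = table.groupby("group")["count"].sum() / total * 100.0
    top = top.reindex([g for g in VALID_GROUPS if g in top.index])

    toxin = table[table["group"] == "toxin"]
    if len(toxin) and toxin["count"].sum() > 0:
        within = toxin.groupby("category")["count"].sum() / toxin["count"].sum() * 100.0
        within = within.sort_values(ascending=False)
    else:
        within = pd.Series(dtype=float)
    return ExpressionProfile(top=top, within_toxin=within)


def plot_profile(prof: ExpressionProfile, path: str) -> None:
    """Write a two-panel pie chart (all reads; toxin families) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    axes[0].pie(prof.top.values, labels=list(prof.top.index), autopct="%.1f%%")
    axes[0].set_title("All mapped reads")
    if len(prof.within_toxin):
        axes[1].pie(
            prof.within_toxin.values,
            labels=list(prof.within_toxin.index),
            autopct="%.1f%%",
        )
    axes[1].set_title("Toxin-like reads by family")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
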