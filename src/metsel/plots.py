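"""Optional figures (requires matplotlib)."""

from __future__ import annotations


def _plt():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def rank_bar(mta, check_names: set[str], path, top: int = 50) -> None:
    """Descending bar chart of predicted yield; checks highlighted."""
    plt = _plt()
    df = mta.predictions.sort_values(
        ["predicted", "genotype"], ascending=[False, True]
    ).head(top + len(check_names))
    colors = ["tab:blue" if g in check_names else "tab:pink" for g in df["genotype"]]
    fig, ax = plt.subplots(figsize=(12, 4))
    ax.bar(range(len(df)), df["predicted"], color=colors)
    ax.set_xticks(range(len(df)))
    ax.set_xticklabels(df["genotype"], rotation=90, fontsize=5)
    ax.set_ylabel(f"predicted {mta.trait}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def index_scatter(mta, scores, check_names: set[str], path) -> None:
    """Predicted yield vs selection-index score."""
    plt = _plt()
    merged = mta.predictions.merge(scores, on="genotype")
    is_check = merged["genotype"].isin(check_names)
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(merged.loc[~is_check, "predicted"], merged.loc[~is_check, "score"],
               s=8, alpha=0.6, label="accessions")
    ax.scatter(merged.loc[is_check, "predicted"], merged.loc[is_check, "score"],
               s=25, color="tab:blue", label="checks")
    ax.set_xlabel(f"predicted {mta.trait}")
    ax.set_ylabel("index score")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
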