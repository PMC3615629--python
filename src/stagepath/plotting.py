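"""Optional plotting helpers (requires matplotlib, ``stagepath[plot]``)."""

from __future__ import annotations

from .markers import IFSCurve


def plot_ifs_curve(curve: IFSCurve, out_path, title: str | None = None) -> None:
    """Accuracy-vs-prefix-size curve with the optimal set highlighted."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ks = range(1, len(curve.accuracies) + 1)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(ks, curve.accuracies, lw=1)
    ax.axvline(curve.optimal_k, color="crimson", ls="--", lw=1)
    ax.annotate(
        f"k={curve.optimal_k}, acc={curve.best_accuracy:.3f}",
        xy=(curve.optimal_k, curve.best_accuracy),
        xytext=(5, -10), textcoords="offset points", fontsize=9,
    )
    ax.set_xlabel("number of top-ranked genes")
    ax.set_ylabel("LOOCV accuracy")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
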