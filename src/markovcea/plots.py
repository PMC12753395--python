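"""Optional figures: tornado diagram, CE plane, acceptability curve."""

from __future__ import annotations

from pathlib import Path


def _axes():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def tornado_plot(entries, baseline_icer: float, path: str | Path) -> None:
    """Horizontal-bar tornado diagram, widest ICER span on top."""
    plt = _axes()
    entries = list(entries)[::-1]  # widest on top after barh
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(entries) + 1.5))
    for i, e in enumerate(entries):
        lo, hi = sorted((e.icer_at_low, e.icer_at_high))
        ax.barh(i, hi - lo, left=lo, color="#4878d0", alpha=0.8)
    ax.axvline(baseline_icer, color="k", lw=1, ls="--", label="baseline ICER")
    ax.set_yticks(range(len(entries)), [e.parameter for e in entries], fontsize=8)
    ax.set_xlabel("ICER (RMB/QALY)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ce_plane(psa_result, wtp: float, path: str | Path) -> None:
    """Incremental cost-effect scatter with the WTP threshold line."""
    plt = _axes()
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(psa_result.delta_effect, psa_result.delta_cost, s=6, alpha=0.4)
    xs = [min(0, psa_result.delta_effect.min()), psa_result.delta_effect.max()]
    ax.plot(xs, [wtp * x for x in xs], "k--", lw=1, label=f"WTP = {wtp:,.0f}")
    ax.axhline(0, color="grey", lw=0.6)
    ax.axvline(0, color="grey", lw=0.6)
    ax.set_xlabel("incremental effect (QALYs)")
    ax.set_ylabel("incremental cost (RMB)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ceac_plot(curve, wtp: float, path: str | Path) -> None:
    """Cost-effectiveness acceptability curve with the WTP landmark."""
    plt = _axes()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.wtp, curve.probability, lw=1.5)
    ax.axvline(wtp, color="k", lw=1, ls="--", label=f"WTP = {wtp:,.0f}")
    ax.set_xlabel("willingness to pay (RMB/QALY)")
    ax.set_ylabel("P(comparator cost-effective)")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
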