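"""Comparison plots for a completed case suite (matplotlib optional).

Generates the standard cross-case figures: separation-vortex length vs
stenosis degree, pressure drop vs stenosis degree (one curve per
rheology), and overlaid wall-pressure / WSS profiles.
"""

from __future__ import annotations

from pathlib import Path


def _require_matplotlib():
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "matplotlib is required for plotting; install the 'plot' extra"
        ) from exc
    return plt


def plot_suite(suite, out_dir) -> list:
    """Write vortex-length, pressure-drop and wall-profile figures.

    Returns the list of files written.  Failed cases are skipped.
    """
    plt = _require_matplotlib()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ok = [r for r in suite.results if r.ok]
    kinds = sorted({r.spec.rheology.kind for r in ok})
    written = []

    def per_kind(metric):
        for kind in kinds:
            rows = sorted(
                (r for r in ok if r.spec.rheology.kind == kind),
                key=lambda r: r.spec.eta,
            )
            yield kind, [r.spec.eta for r in rows], [metric(r.summary) for r in rows]

    for fname, metric, ylabel in (
        ("vortex_length_vs_eta.png",
         lambda s: s.vortex_length_over_R, "vortex length / R"),
        ("pressure_drop_vs_eta.png",
         lambda s: s.delta_p, "pressure drop over [-3R, 9R] [Pa]"),
        ("wss_peak_vs_eta.png",
         lambda s: s.wss_peak, "WSS peak [Pa]"),
    ):
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for kind, etas, vals in per_kind(metric):
            ax.plot(etas, vals, "o-", label=kind)
        ax.set_xlabel("stenosis degree eta")
        ax.set_ylabel(ylabel)
        ax.legend()
        fig.tight_layout()
        path = out_dir / fname
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)

    for fname, xs, ys, ylabel in (
        ("wall_pressure_profiles.png",
         lambda s: s.wall_pressure_x, lambda s: s.wall_pressure,
         "wall pressure [Pa]"),
        ("wss_profiles.png",
         lambda s: s.wall_x, lambda s: s.wss_profile, "WSS [Pa]"),
    ):
        fig, ax = plt.subplots(figsize=(6, 3.5))
        for r in ok:
            R = r.spec.R
            x = xs(r.summary) / R
            ax.plot(x, ys(r.summary), lw=1,
                    label=f"eta={r.spec.eta:g} {r.spec.rheology.kind}")
        ax.set_xlim(-3, 9)
        ax.set_xlabel("x / R")
        ax.set_ylabel(ylabel)
        ax.legend(fontsize=6, ncol=2)
        fig.tight_layout()
        path = out_dir / fname
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)
    return written
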