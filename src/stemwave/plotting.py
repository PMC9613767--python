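"""Figures: kymographs, manifold phase portraits, speed-vs-alpha curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .manifold import SlowManifold
from .pde import solve_fast
from .waves import theoretical_speed

__all__ = ["render_kymograph", "manifold_phase_portrait", "speed_vs_alpha_plot"]


def render_kymograph(times, x, profiles, out_path, cmap="viridis",
                     xlabel="x", tlabel="t", title=None):
    """Space-time heatmap of a density profile sequence.

    The boundary between the high- and low-density regions appears as a
    straight line whose inverse slope is the front speed.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 snapshots for a kymograph")
    fig, ax = plt.subplots(figsize=(7, 4))
    im = ax.imshow(
        profiles, aspect="auto", origin="lower", cmap=cmap,
        extent=[x[0], x[-1], times[0], times[-1]],
    )
    fig.colorbar(im, ax=ax, label="density")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(tlabel)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def manifold_phase_portrait(alpha, F="linear", out_path=None,
                            n_orbits=6, t_end=40.0):
    """Slow manifold in the (u, v) plane with fast-system orbits.

    Orbits started off the manifold relax vertically onto it (u is frozen
    on the fast scale).
    """
    man = SlowManifold(alpha, F)
    u = np.linspace(0.0, 1.0, 400)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(u, man.v(u), color="deeppink", lw=2,
            label=rf"slow manifold $v_\alpha(u)$, $\alpha$={alpha}")
    rng = np.random.default_rng(0)
    for _ in range(n_orbits):
        u0 = float(rng.uniform(0.05, 0.9))
        v0 = float(rng.uniform(0.0, 1.0 - u0))
        ts, vs = solve_fast(u0, v0, alpha, F, t_end=t_end)
        ax.plot(np.full_like(vs, u0), vs, color="tab:blue", lw=0.8)
        ax.plot([u0], [vs[-1]], "k.", ms=3)
    ax.set_xlabel("u (stem cells)")
    ax.set_ylabel("v (non-stem cells)")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
        return out_path
    return fig


def speed_vs_alpha_plot(alphas, measured, d=1.0, out_path=None):
    """Measured front speeds against the closed-form minimal speed."""
    alphas = np.asarray(alphas, dtype=float)
    aa = np.linspace(min(alphas.min(), 0.01), max(alphas.max(), 1.5), 300)
    theory = [theoretical_speed(a, d) for a in aa]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(aa, theory, "k-", label=r"$\sigma^*=2\sqrt{dF(v^*_\alpha)}$")
    ax.plot(alphas, measured, "o", color="tab:red", label="measured")
    ax.set_xlabel(r"death rate $\alpha$")
    ax.set_ylabel("front speed")
    ax.legend()
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
        return out_path
    return fig
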