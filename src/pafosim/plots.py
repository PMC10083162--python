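"""Basic line plots of sweep results and cycle series."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_overall_effect(report, path, situation="mass_and_actuation") -> None:
    """Overall effect vs device mass, one line per actuator position."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for pos in report.spec.positions:
        masses = list(report.spec.masses)
        y = [report.overall_effect(situation, pos, m) for m in masses]
        ax.plot(masses, y, marker="o", label=pos)
    ax.set_xlabel("device mass [kg]")
    ax.set_ylabel("overall muscle-force-integral change [%]")
    ax.set_title(f"situation: {situation}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_moments(series_by_label: dict, path) -> None:
    """Net joint moment curves over the gait cycle, one panel per joint."""
    joints = ("hip", "knee", "ankle")
    fig, axes = plt.subplots(1, 3, figsize=(11, 3.2), sharex=True)
    for ax, j in zip(axes, joints):
        for label, series in series_by_label.items():
            ax.plot(series.percent, series.moments[j], label=label, lw=1)
        ax.set_title(j)
        ax.set_xlabel("gait cycle [%]")
    unit = "N·m/kg" if next(iter(series_by_label.values())).normalized else "N·m"
    axes[0].set_ylabel(f"net internal moment [{unit}]")
    axes[-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_muscle_forces(forces, path, muscles=None) -> None:
    """Muscle force curves over the gait cycle."""
    names = muscles if muscles is not None else forces.muscle_names
    fig, ax = plt.subplots(figsize=(7, 4))
    for nm in names:
        ax.plot(forces.percent, forces.force(nm), label=nm, lw=1)
    ax.set_xlabel("gait cycle [%]")
    ax.set_ylabel("muscle force [N/kg]" if forces.normalized else "muscle force [N]")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
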