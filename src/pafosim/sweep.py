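"""Full device sweep: subjects × actuator positions × masses × situations.

For every subject the pipeline is: synthetic gait (multi-cycle average) →
forward markers → inverse kinematics → differentiation → per-configuration
inverse dynamics → static optimization → metrics.  The no-device baseline
is computed once per subject; the actuation-only situation shares the
baseline moments (no added mass), and every mass-bearing cell rebuilds the
model from the pristine baseline before the orthosis mass is applied.

Aggregation follows: normalize to body mass per subject → per-subject
muscle force integrals and peak moments → average across subjects →
percentage change of the averages against the no-device baseline.  The
alternative order (per-subject percentage change, then average) is
available behind ``per_subject_changes``.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._fk import JOINT_NAMES
from .inverse_dynamics import differentiate, inverse_dynamics, peak_moments
from .inverse_kinematics import solve_ik
from .metrics import (average_subjects, muscle_force_integral, overall_effect,
                      percentage_change)
from .msk_model import (POSITION_LABELS, LowerLimbModel, PAFOConfig,
                        Situation, apply_pafo, scale_model)
from .static_optimization import run_static_optimization
from .subjects import SubjectSpec, synthetic_panel
from .synthetic_gait import GaitParams, forward_markers, generate_averaged_gait

log = logging.getLogger(__name__)

DEFAULT_MASSES = (1.0, 2.0, 3.0, 4.0, 5.0)


@dataclass
class SweepSpec:
    """What to sweep: subject panel, device masses, positions, situations."""

    subjects: list = field(default_factory=list)   # list[SubjectSpec]
    masses: tuple = DEFAULT_MASSES
    positions: tuple = POSITION_LABELS
    situations: tuple = tuple(Situation)
    seed: int = 0
    n_cycles: int = 31
    marker_noise_sd: float = 0.002
    lateral_offset: float = 0.05
    posterior_offset: float = 0.05
    per_subject_changes: bool = False
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.subjects:
            self.subjects = synthetic_panel(10, self.seed)
        self.situations = tuple(Situation(s) if isinstance(s, str) else s
                                for s in self.situations)
        if not self.masses or not self.positions or not self.situations:
            raise ValueError("masses, positions and situations must be non-empty")
        if any(m < 0 for m in self.masses):
            raise ValueError("device masses must be >= 0")


@dataclass
class SubjectResult:
    """Per-subject pipeline products (body-mass-normalized metrics)."""

    spec: SubjectSpec
    ik_rms: float
    integrals: dict        # cell -> (n_muscles,) normalized force integrals
    reserve_integrals: dict  # cell -> float
    peaks: dict            # cell -> {joint: (peak_pos, peak_neg)}
    infeasible: dict       # cell -> frame count
    errors: dict           # cell -> message


Cell = tuple[str, str, float]   # (situation value, position, mass)


def make_cell(situation: Situation, position: str, mass: float) -> Cell:
    """Canonical cell key; mass-free situations collapse onto one cell.

    Without mass the device position is irrelevant (the actuation-only
    reserve acts at the ankle regardless), so those situations map to a
    single position-independent cell.
    """
    if not situation.has_mass:
        return (situation.value, "-", 0.0)
    return (situation.value, position, float(mass))


@dataclass
class SweepReport:
    """Aggregated sweep results with metric lookups."""

    spec: SweepSpec
    subject_results: list
    muscle_names: list
    muscle_tags: dict

    def __post_init__(self) -> None:
        self._mean_integrals = {}
        cells = set()
        for sr in self.subject_results:
            cells.update(sr.integrals)
        for cell in cells:
            arrs = [sr.integrals[cell] for sr in self.subject_results
                    if cell in sr.integrals]
            self._mean_integrals[cell] = np.mean(arrs, axis=0)

    # -- lookups --------------------------------------------------------
    def cells(self) -> list:
        return sorted(self._mean_integrals)

    def mean_integrals(self, situation, position, mass) -> np.ndarray:
        return self._mean_integrals[make_cell(Situation(situation), position,
                                              mass)]

    def _baseline_integrals(self) -> np.ndarray:
        key = next(k for k in self._mean_integrals
                   if k[0] == Situation.NO_PAFO.value)
        return self._mean_integrals[key]

    def muscle_changes(self, situation, position, mass) -> dict:
        """Per-muscle percentage change of the force integral vs baseline."""
        situation = Situation(situation)
        if self.spec.per_subject_changes:
            per_subj = []
            for sr in self.subject_results:
                base = next(v for k, v in sr.integrals.items()
                            if k[0] == Situation.NO_PAFO.value)
                cell = make_cell(situation, position, mass)
                if cell not in sr.integrals:
                    continue
                per_subj.append([percentage_change(b, v) for b, v in
                                 zip(base, sr.integrals[cell])])
            mean = np.mean(per_subj, axis=0)
            return dict(zip(self.muscle_names, mean))
        base = self._baseline_integrals()
        comp = self.mean_integrals(situation, position, mass)
        return {n: percentage_change(b, v)
                for n, b, v in zip(self.muscle_names, base, comp)}

    def overall_effect(self, situation, position, mass) -> float:
        """Mean force-integral change over non-excluded muscles (%)."""
        return overall_effect(self.muscle_changes(situation, position, mass),
                              self.muscle_tags)

    def mean_peaks(self, situation, position, mass) -> dict:
        situation = Situation(situation)
        cell = make_cell(situation, position, mass)
        out = {}
        for j in JOINT_NAMES:
            vals = np.array([sr.peaks[cell][j] for sr in self.subject_results
                             if cell in sr.peaks])
            out[j] = tuple(vals.mean(axis=0))
        return out

    def peak_moment_changes(self, situation, position, mass) -> dict:
        """%change of subject-averaged peak moments vs baseline, per joint.

        Returns joint -> (positive-direction peak change, negative-direction
        peak change).
        """
        base = self.mean_peaks(Situation.NO_PAFO, position, 0.0)
        comp = self.mean_peaks(situation, position, mass)
        return {j: (percentage_change(base[j][0], comp[j][0]),
                    percentage_change(base[j][1], comp[j][1]))
                for j in JOINT_NAMES}

    def rank_positions(self, mass, situation) -> list:
        """Positions sorted ascending by overall effect (stable ties)."""
        situation = Situation(situation)
        effects = []
        for pos in self.spec.positions:
            cell = make_cell(situation, pos, mass)
            if cell not in self._mean_integrals:
                raise KeyError(f"sweep has no cell for {pos}, {mass}, "
                               f"{situation.value}")
            effects.append(self.overall_effect(situation, pos, mass))
        order = np.argsort(effects, kind="stable")
        return [self.spec.positions[i] for i in order]

    # -- tabular output -------------------------------------------------
    def overall_table(self) -> pd.DataFrame:
        rows = []
        for sit in self.spec.situations:
            for pos in self.spec.positions:
                for mass in self.spec.masses:
                    rows.append({
                        "situation": sit.value, "position": pos,
                        "mass": float(mass),
                        "overall_effect":
                            self.overall_effect(sit, pos, mass)})
        return pd.DataFrame(rows)

    def muscle_table(self) -> pd.DataFrame:
        """Rows = muscles plus 'overall'; columns = position × mass × situation."""
        cols = {}
        for sit in self.spec.situations:
            for pos in self.spec.positions:
                for mass in self.spec.masses:
                    key = f"{pos}_{mass:g}kg_{sit.value}"
                    ch = self.muscle_changes(sit, pos, mass)
                    col = [ch[n] for n in self.muscle_names]
                    col.append(self.overall_effect(sit, pos, mass))
                    cols[key] = col
        return pd.DataFrame(cols, index=list(self.muscle_names) + ["overall"])

    def to_json(self) -> str:
        payload = {
            "seed": self.spec.seed,
            "subjects": [sr.spec.subject_id for sr in self.subject_results],
            "overall": self.overall_table().to_dict(orient="records"),
            "ik_rms": {sr.spec.subject_id: sr.ik_rms
                       for sr in self.subject_results},
            "infeasible_frames": {
                sr.spec.subject_id: int(sum(sr.infeasible.values()))
                for sr in self.subject_results},
            "errors": {sr.spec.subject_id: sr.errors
                       for sr in self.subject_results if sr.errors},
        }
        return json.dumps(payload, indent=2)

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.muscle_table().to_csv(out / "muscle_changes.csv")
        self.overall_table().to_csv(out / "overall_effect.csv", index=False)
        (out / "report.json").write_text(self.to_json())


def _simulate_subject(spec: SubjectSpec, sweep: SweepSpec) -> SubjectResult:
    t0 = time.perf_counter()
    model = scale_model(spec.height, spec.mass, spec.subject_id)
    params = GaitParams.subject_variant(spec.seed,
                                        marker_noise_sd=sweep.marker_noise_sd)
    cycle = generate_averaged_gait(model, params, sweep.n_cycles)
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 17)))
    forward_markers(model, cycle, sweep.marker_noise_sd, rng=rng)
    ik = solve_ik(cycle.markers, model)
    angles = dict(ik.angles)
    derivs = differentiate(angles, cycle.cycle_duration)
    grf = cycle.grf["right"]

    integrals: dict = {}
    reserve_ints: dict = {}
    peaks: dict = {}
    infeasible: dict = {}
    errors: dict = {}

    def store(cell, moments, forces):
        nm = moments.normalize_to_body_mass(spec.mass)
        nf = forces.normalize_to_body_mass(spec.mass)
        integrals[cell] = np.array([
            muscle_force_integral(nf.forces[:, i], nf.percent)
            for i in range(nf.forces.shape[1])])
        reserve_ints[cell] = muscle_force_integral(nf.reserve, nf.percent)
        peaks[cell] = peak_moments(nm)
        infeasible[cell] = int(np.sum(~forces.feasible))

    # baseline and actuation-only share the unmodified model's moments
    base_moments = inverse_dynamics(model, angles, derivs, grf)
    for sit in (Situation.NO_PAFO, Situation.ACTUATION_ONLY):
        if sit not in sweep.situations:
            continue
        cell = make_cell(sit, sweep.positions[0], 0.0)
        try:
            forces = run_static_optimization(
                model, angles, derivs, base_moments,
                PAFOConfig(total_mass=0.0, position=sweep.positions[0],
                           situation=sit))
            store(cell, base_moments, forces)
        except Exception as exc:  # keep sweeping other cells
            errors[cell] = str(exc)
            log.warning("subject %s cell %s failed: %s",
                        spec.subject_id, cell, exc)

    mass_sits = [s for s in sweep.situations if s.has_mass]
    for pos in sweep.positions:
        for mass in sweep.masses:
            pafo_model = None
            cell_moments = None
            for sit in mass_sits:
                cell = make_cell(sit, pos, mass)
                try:
                    cfg = PAFOConfig(
                        total_mass=float(mass), position=pos, situation=sit,
                        lateral_offset=sweep.lateral_offset,
                        posterior_offset=sweep.posterior_offset)
                    if pafo_model is None:
                        # rebuild from the pristine model for every cell
                        pafo_model = apply_pafo(model, cfg)
                        cell_moments = inverse_dynamics(
                            pafo_model, angles, derivs, grf)
                    forces = run_static_optimization(
                        pafo_model, angles, derivs, cell_moments, cfg)
                    store(cell, cell_moments, forces)
                except Exception as exc:
                    errors[cell] = str(exc)
                    log.warning("subject %s cell %s failed: %s",
                                spec.subject_id, cell, exc)

    log.info("subject %s done in %.2f s (%d infeasible frames)",
             spec.subject_id, time.perf_counter() - t0,
             sum(infeasible.values()))
    return SubjectResult(spec=spec, ik_rms=float(np.max(ik.rms)),
                         integrals=integrals, reserve_integrals=reserve_ints,
                         peaks=peaks, infeasible=infeasible, errors=errors)


def run_sweep(spec: SweepSpec | None = None, **kwargs) -> SweepReport:
    """Run the full sweep and aggregate across subjects.

    Deterministic for a given spec (all randomness flows from the spec and
    per-subject seeds).  Per-cell failures are recorded and the sweep
    continues.
    """
    spec = spec if spec is not None else SweepSpec(**kwargs)
    results = [_simulate_subject(s, spec) for s in spec.subjects]
    template = scale_model(spec.subjects[0].height, spec.subjects[0].mass)
    names = [m.name for m in template.muscles]
    tags = {m.name: m.groups for m in template.muscles}
    report = SweepReport(spec=spec, subject_results=results,
                         muscle_names=names, muscle_tags=tags)
    if spec.output_dir:
        report.save(spec.output_dir)
    return report


def rank_positions(report: SweepReport, mass, situation) -> list:
    """Module-level convenience mirroring ``SweepReport.rank_positions``."""
    return report.rank_positions(mass, situation)
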