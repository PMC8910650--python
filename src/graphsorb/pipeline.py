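"""Study orchestration: build -> place -> minimize -> SMD -> relax ->
analyze -> report, with replicates and paired statistical comparison.

A study runs the full adsorption protocol for each seed in
``RunConfig.seeds`` and aggregates the analysis products: adsorption
energy / RMSD / radius-of-gyration time series, per-residue contact
tables, Ramachandran records, secondary-structure content, and — with
two or more replicates per condition — paired t-tests between
conditions (raw and Holm-adjusted p-values are both reported).

SMD durations follow the per-pattern protocol durations (deeper
topographies need longer pulls); ``SMD_DURATIONS_PS`` holds the
full-scale protocol values and ``TOY_SMD_DURATIONS_PS`` the desk-scale
equivalents used with the miniature substrates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from graphsorb import conformation as conf
from graphsorb import energetics as en
from graphsorb import simulate as sim
from graphsorb import synthetic as syn

__all__ = [
    "RunConfig",
    "AnalysisReport",
    "run_study",
    "analyze_trajectory",
    "compare_replicates",
    "SMD_DURATIONS_PS",
    "TOY_SMD_DURATIONS_PS",
]

#: Full-scale protocol SMD durations per pattern (ps)
SMD_DURATIONS_PS = {"flat": 8.0, "LN1": 32.0, "LN2": 32.0, "CS1": 40.0, "CS2": 32.0, "SQ": 96.0}

#: Desk-scale SMD durations for the miniature presets (ps); longer for
#: recessed topographies, mirroring the protocol's pattern-dependent times
TOY_SMD_DURATIONS_PS = {"flat": 44.0, "LN1": 84.0, "LN2": 84.0, "CS1": 76.0,
                        "CS2": 100.0, "SQ": 84.0}


@dataclass
class RunConfig:
    """Configuration of one study condition.

    ``protein`` is either ``fixture:toy_dimer`` (bead-spring homodimer)
    or a path to a PDB file; ``pattern`` is a miniature preset name
    (flat, LN1, LN2, CS1, CS2, SQ).  ``smd_duration`` of None selects
    the per-pattern default.
    """

    pattern: str = "flat"
    protein: str = "fixture:toy_dimer"
    n_per_chain: int = 24
    extent: tuple = (60.0, 60.0, 32.0)
    gap: float = 12.0
    smd_k: float = 167.36
    smd_v: float = 0.25
    smd_duration: float | None = None
    relax_duration: float = 80.0
    temperature: float = 310.0
    gamma: float = 1.0
    dt: float = 0.004
    stride: int = 2500
    seeds: tuple = (0, 1, 2)
    outdir: str | None = None
    analyses: tuple = ("energy", "rmsd", "rg", "contacts", "ramachandran", "ss")

    def __post_init__(self) -> None:
        if not self.seeds:
            raise ValueError("at least one seed required")
        if self.relax_duration <= 0 or (self.smd_duration is not None and self.smd_duration <= 0):
            raise ValueError("durations must be positive")

    @property
    def resolved_smd_duration(self) -> float:
        if self.smd_duration is not None:
            return self.smd_duration
        return TOY_SMD_DURATIONS_PS.get(self.pattern, 44.0)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        extra = set(raw) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        for key in ("extent", "seeds", "analyses"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class AnalysisReport:
    """Aggregated products of a study run."""

    config: RunConfig
    per_seed: dict = field(default_factory=dict)   # seed -> {"energy": df, ...}
    final_energies: dict = field(default_factory=dict)  # seed -> kJ/mol
    manifest: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        vals = np.array(list(self.final_energies.values()))
        return pd.DataFrame({
            "n": [len(vals)],
            "mean_energy": [vals.mean() if len(vals) else np.nan],
            "sd_energy": [vals.std(ddof=1) if len(vals) > 1 else np.nan],
            "mean_abs_energy": [np.abs(vals).mean() if len(vals) else np.nan],
        })


def _build_system(config: RunConfig, seed: int):
    if config.protein.startswith("fixture:"):
        kind = config.protein.split(":", 1)[1]
        if kind != "toy_dimer":
            raise ValueError(f"unknown fixture {kind!r}")
        return syn.make_toy_dimer_system(config.pattern, n_per_chain=config.n_per_chain,
                                         seed=seed, gap=config.gap, extent=config.extent)
    from graphsorb.lattice import build_flat, carve_pattern, LatticeSpec, PATTERN_PRESETS
    from graphsorb.protein import read_pdb, assign_protonation, place_above_substrate

    model = assign_protonation(read_pdb(config.protein))
    lattice = carve_pattern(build_flat(LatticeSpec(target_extent=config.extent)),
                            PATTERN_PRESETS[config.pattern])
    return place_above_substrate(model, lattice, gap=config.gap)


def analyze_trajectory(system, traj: conf.Trajectory, analyses=None) -> dict:
    """All enabled conformation/energy analyses for one trajectory.

    Works identically for inline pipeline runs and analysis-only mode
    on a stored trajectory.
    """
    analyses = analyses or ("energy", "rmsd", "rg", "contacts", "ramachandran", "ss")
    out: dict = {}
    prot = system.protein
    base_coords = prot.coords.copy()

    if "energy" in analyses:
        rows = []
        for t, frame in zip(traj.times, traj.frames):
            prot.coords = frame
            e = en.adsorption_energy(system, time=float(t))
            rows.append({"time": t, "vdw": e.vdw, "coulomb": e.coulomb, "total": e.total})
        out["energy"] = pd.DataFrame(rows)
    if "rmsd" in analyses:
        out["rmsd"] = pd.DataFrame({"time": traj.times, "rmsd": conf.rmsd(traj)})
    if "rg" in analyses:
        out["rg"] = pd.DataFrame({"time": traj.times,
                                  "rg": conf.rg_series(traj, prot.masses)})
    if "contacts" in analyses:
        prot.coords = traj.frames[-1]
        final = en.residue_contacts(system)
        peak = final["contacts"].to_numpy().copy()
        for frame in traj.frames:
            prot.coords = frame
            peak = np.maximum(peak, en.residue_contacts(system)["contacts"].to_numpy())
        final["contacts_peak"] = peak
        out["contacts"] = final

    has_backbone = bool(np.isin(("N", "C"), prot.atoms.atom_name).all())
    if "ramachandran" in analyses and has_backbone:
        out["ramachandran_initial"] = conf.ramachandran_records(prot, traj.frames[0])
        out["ramachandran_final"] = conf.ramachandran_records(prot, traj.frames[-1])
    if "ss" in analyses and has_backbone:
        ss0 = conf.assign_secondary_structure(prot, traj.frames[0])
        ss1 = conf.assign_secondary_structure(prot, traj.frames[-1])
        out["ss_initial"] = conf.ss_content_table(ss0)
        out["ss_final"] = conf.ss_content_table(ss1)

    prot.coords = base_coords
    return out


def run_study(config: RunConfig) -> AnalysisReport:
    """Execute minimize -> SMD -> relax -> analyze for every seed.

    Re-running with the same config and seeds reproduces outputs
    bit-identically.  If ``config.outdir`` is set, CSV metrics, the
    final structure and a JSON manifest are written there.
    """
    report = AnalysisReport(config=config)
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    for seed in config.seeds:
        try:
            system = _build_system(config, seed)
            system = sim.minimize(system, max_steps=200)
            thermo = sim.ThermostatParams(T=config.temperature, gamma=config.gamma, seed=seed)
            smd = sim.SMDParams(k=config.smd_k, v=config.smd_v,
                                duration=config.resolved_smd_duration)
            system, traj_smd, log_smd = sim.run_smd(system, smd, thermo,
                                                    dt=config.dt, stride=config.stride)
            system, traj_rlx, log_rlx = sim.run_relaxation(system, config.relax_duration,
                                                           thermo, dt=config.dt,
                                                           stride=config.stride)
        except Exception as exc:
            raise RuntimeError(f"stage failure for seed {seed}: {exc}") from exc

        frames = np.concatenate([traj_smd.frames, traj_rlx.frames[1:]])
        times = np.concatenate([traj_smd.times,
                                traj_smd.times[-1] + traj_rlx.times[1:]])
        traj = conf.Trajectory(frames, times, meta={"seed": seed})
        results = analyze_trajectory(system, traj, config.analyses)
        results["smd_log"] = log_smd
        results["relax_log"] = log_rlx
        report.per_seed[seed] = results
        report.final_energies[seed] = float(results["energy"]["total"].iloc[-1]) \
            if "energy" in results else float("nan")

        if outdir:
            for name, df in results.items():
                df.to_csv(outdir / f"seed{seed}_{name}.csv", index=("ss" in name))
            traj.write_xyz(outdir / f"seed{seed}_traj.xyz",
                           elements=list(system.protein.atoms.element))

    report.manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "smd_duration_ps": config.resolved_smd_duration,
        "final_energies": report.final_energies,
    }
    if outdir:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(report.manifest, fh, indent=2)
    return report


def adsorption_ranking_study(seeds=(0, 1, 2, 3, 4),
                             conditions=("flat", "SQ", "CS2"),
                             **config_overrides) -> dict:
    """Post-relaxation adsorption energies per condition over paired seeds.

    Runs the full minimize -> SMD -> relax protocol for every
    (condition, seed) pair with the per-pattern SMD durations and
    returns {condition: [final energy per seed]} for replicate
    comparison and ranking by mean |E|.
    """
    energies: dict = {}
    for pattern in conditions:
        config = RunConfig(pattern=pattern, seeds=tuple(seeds),
                           analyses=("energy",), **config_overrides)
        report = run_study(config)
        energies[pattern] = [report.final_energies[s] for s in seeds]
    return energies


def compare_replicates(energies: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise paired t-tests between conditions.

    ``energies`` maps condition name -> replicate energy vector; the
    replicates of each condition must be paired by seed (equal length,
    same order).  Returns one row per condition pair with the paired t
    statistic, raw two-sided p, Holm-adjusted p and significance flags.
    """
    names = list(energies)
    if len(names) < 2:
        raise ValueError("need at least two conditions")
    lengths = {len(v) for v in energies.values()}
    if len(lengths) != 1:
        raise ValueError("replicate counts must match across conditions")
    n = lengths.pop()
    if n < 2:
        raise ValueError("need at least two replicates per condition")

    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a = np.asarray(energies[names[i]], dtype=float)
            b = np.asarray(energies[names[j]], dtype=float)
            diff = a - b
            if np.allclose(diff, diff[0]):
                if np.allclose(diff, 0.0):
                    t, p = 0.0, 1.0  # identical vectors: no difference
                else:
                    t, p = np.inf, 0.0  # constant nonzero shift: zero variance
            else:
                t, p = stats.ttest_rel(a, b)
            rows.append({"condition_a": names[i], "condition_b": names[j],
                         "mean_a": a.mean(), "mean_b": b.mean(),
                         "sd_a": a.std(ddof=1), "sd_b": b.std(ddof=1),
                         "t": float(t), "p": float(p)})
    df = pd.DataFrame(rows)
    # Holm step-down adjustment
    order = np.argsort(df["p"].to_numpy())
    m = len(df)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * df["p"].iloc[idx])
        adj[idx] = min(1.0, running)
    df["p_holm"] = adj
    df["significant"] = df["p"] < alpha
    df["significant_holm"] = df["p_holm"] < alpha
    return df
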