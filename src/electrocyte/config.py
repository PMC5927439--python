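"""Configuration loading/validation, serialization and fixture generation.

Configs are flat YAML (JSON is valid YAML and therefore accepted):

.. code-block:: yaml

    profile: epm-default
    overrides: {g_na_max: 783.0}
    regime:
      syn: {pulse: {amp: 1.0, freq_hz: 400.0}, background: 0.0}
      duration_ms: 100.0
    solver: {dt_ms: 0.0005, sample_dt_ms: 0.002}
    seed: 0          # reserved; the core model is deterministic

Unknown keys are rejected and all physical values are validated by the domain
types before any run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional

import yaml

from .params import PROFILES, ModelParams, epm_default
from .simulate import SolverOptions
from .stimulus import (BackgroundSynDrive, CurrentClampDrive,
                       PulsatileSynDrive, StimulusRegime)


class ConfigError(ValueError):
    """Raised with an itemized list of configuration problems."""

    def __init__(self, problems: List[str]):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n" +
                         "\n".join(f"  - {p}" for p in self.problems))


@dataclass(frozen=True)
class RunConfig:
    """Validated run description: parameters + regime + solver options."""

    params: ModelParams
    regime: Optional[StimulusRegime]
    duration: float
    solver: SolverOptions
    seed: int = 0
    profile: str = "epm-default"


def _check_keys(mapping: dict, allowed: set, context: str, problems: list):
    for key in mapping:
        if key not in allowed:
            problems.append(f"unknown key {key!r} in {context}")


def params_from_config(doc: dict, problems: list) -> Optional[ModelParams]:
    profile = doc.get("profile", "epm-default")
    if profile not in PROFILES:
        problems.append(f"unknown profile {profile!r}; "
                        f"known: {sorted(PROFILES)}")
        return None
    params = PROFILES[profile]()
    overrides = doc.get("overrides") or {}
    if not isinstance(overrides, dict):
        problems.append("overrides must be a mapping")
        return None
    flat_fields = {f.name for f in dataclasses.fields(ModelParams)
                   if f.type in ("float", "int")} | {
                       "capacitance", "g_na_max", "g_k_max", "g_leak", "gamma",
                       "e_na", "e_k", "e_leak", "temperature"}
    conc_fields = {"na_in", "na_out", "k_in", "k_out"}
    syn_fields = {"p_na", "pk_over_pna"}
    try:
        for key, value in overrides.items():
            if key in flat_fields:
                params = dataclasses.replace(params, **{key: float(value)})
            elif key in conc_fields:
                params = dataclasses.replace(
                    params, concentrations=dataclasses.replace(
                        params.concentrations, **{key: float(value)}))
            elif key in syn_fields:
                params = dataclasses.replace(
                    params, synapse=dataclasses.replace(
                        params.synapse, **{key: float(value)}))
            else:
                problems.append(f"unknown parameter override {key!r}")
    except ValueError as err:
        problems.append(str(err))
        return None
    return params


def regime_from_config(doc: dict, problems: list) -> Optional[StimulusRegime]:
    _check_keys(doc, {"syn", "clamp", "duration_ms"}, "regime", problems)
    pulsatile = background = clamp = None
    try:
        syn = doc.get("syn")
        if syn is not None:
            _check_keys(syn, {"pulse", "background"}, "regime.syn", problems)
            pulse = syn.get("pulse")
            if pulse is not None:
                allowed = {"amp", "freq_hz", "rise_ms", "plateau_ms", "tau_ms"}
                _check_keys(pulse, allowed, "regime.syn.pulse", problems)
                pulsatile = PulsatileSynDrive(
                    amplitude=float(pulse["amp"]),
                    frequency=float(pulse["freq_hz"]),
                    rise=float(pulse.get("rise_ms", 0.05)),
                    plateau=float(pulse.get("plateau_ms", 0.200)),
                    decay_tau=float(pulse.get("tau_ms", 0.1)))
            bg = syn.get("background")
            if bg is not None:
                background = BackgroundSynDrive(level=float(bg))
        cl = doc.get("clamp")
        if cl is not None:
            allowed = {"kind", "amplitude_na", "duration_ms", "start_ms",
                       "pulse_width_ms", "freq_hz"}
            _check_keys(cl, allowed, "regime.clamp", problems)
            clamp = CurrentClampDrive(
                kind=cl["kind"], amplitude=float(cl["amplitude_na"]),
                duration=float(cl["duration_ms"]),
                start=float(cl.get("start_ms", 0.0)),
                pulse_width=(float(cl["pulse_width_ms"])
                             if "pulse_width_ms" in cl else None),
                frequency=(float(cl["freq_hz"]) if "freq_hz" in cl else None))
        if problems:
            return None
        return StimulusRegime(pulsatile=pulsatile, background=background,
                              clamp=clamp)
    except (KeyError, TypeError, ValueError) as err:
        problems.append(f"regime: {err}")
        return None


def load_config(path) -> RunConfig:
    """Load and fully validate a YAML/JSON run configuration."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(["top level must be a mapping"])
    problems: List[str] = []
    _check_keys(doc, {"profile", "overrides", "regime", "solver", "seed"},
                "top level", problems)
    params = params_from_config(doc, problems)
    regime = None
    duration = 100.0
    if "regime" in doc:
        rdoc = dict(doc["regime"])
        duration = float(rdoc.get("duration_ms", 100.0))
        regime = regime_from_config(rdoc, problems)
    solver = SolverOptions()
    if "solver" in doc:
        sdoc = doc["solver"]
        _check_keys(sdoc, {"dt_ms", "sample_dt_ms"}, "solver", problems)
        try:
            solver = SolverOptions(dt=float(sdoc.get("dt_ms", 5e-4)),
                                   sample_dt=float(sdoc.get("sample_dt_ms", 2e-3)))
        except ValueError as err:
            problems.append(f"solver: {err}")
    if problems or params is None:
        raise ConfigError(problems or ["no valid parameter set"])
    return RunConfig(params=params, regime=regime, duration=duration,
                     solver=solver, seed=int(doc.get("seed", 0)),
                     profile=doc.get("profile", "epm-default"))


def params_to_dict(params: ModelParams) -> dict:
    """Flat serialization of a parameter set (round-trips via overrides)."""
    return {
        "capacitance": params.capacitance, "g_na_max": params.g_na_max,
        "g_k_max": params.g_k_max, "g_leak": params.g_leak,
        "gamma": params.gamma, "e_na": params.e_na, "e_k": params.e_k,
        "e_leak": params.e_leak, "temperature": params.temperature,
        "na_in": params.concentrations.na_in,
        "na_out": params.concentrations.na_out,
        "k_in": params.concentrations.k_in,
        "k_out": params.concentrations.k_out,
        "p_na": params.synapse.p_na,
        "pk_over_pna": params.synapse.pk_over_pna,
    }


def write_run_log(path, config: RunConfig) -> None:
    """Record the exact resolved parameters and solver options of a run."""
    log = {
        "profile": config.profile,
        "params": params_to_dict(config.params),
        "solver": {"dt_ms": config.solver.dt,
                   "sample_dt_ms": config.solver.sample_dt},
        "duration_ms": config.duration,
        "seed": config.seed,
    }
    with open(path, "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)


def generate_fixtures(output_dir) -> List[Path]:
    """Write reference fixtures: the 18 cost-table regime configs, the
    staircase scan description, and short golden trajectories at 200 and
    600 Hz (standard pulsatile drive, calibrated conductances).

    Returns the list of files written.  All outputs are plain text.
    """
    from .protocols import TABLE_REGIMES, pulsatile_regime
    from .simulate import integrate

    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for i, (freq, bg, amp) in enumerate(TABLE_REGIMES, start=1):
        doc = {"profile": "epm-default",
               "regime": {"syn": {"background": bg}, "duration_ms": 200.0}}
        if amp > 0:
            doc["regime"]["syn"]["pulse"] = {"amp": amp, "freq_hz": freq}
        path = outdir / f"regime_{i:02d}_{int(freq)}hz.yaml"
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)
        written.append(path)

    scan = {"profile": "epm-default", "staircase": {
        "background": 0.00736, "pulse_freq_hz": 200.0,
        "amplitude_start": 0.0, "amplitude_stop": 0.5, "amplitude_step": 0.005}}
    path = outdir / "staircase_scan.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(scan, fh, sort_keys=True)
    written.append(path)

    for freq, gna in ((200.0, 700.0), (600.0, 1126.0)):
        params = epm_default().with_g_na_max(gna)
        period = 1000.0 / freq
        traj = integrate(params, pulsatile_regime(1.0, freq), 3 * period)
        path = outdir / f"golden_{int(freq)}hz.csv"
        traj.to_csv(path)
        written.append(path)
    return written


def file_checksum(path) -> str:
    """SHA-256 of a file, for fixture determinism checks."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
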