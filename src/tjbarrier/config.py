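"""Run configuration, orchestration and result files.

A :class:`RunConfig` fully specifies a simulation (model, epithelium,
geometry/dynamics overrides, horizon, replicates, seed) and round-trips
through YAML.  :func:`run` executes it and writes a deterministic summary
JSON, trace CSVs and a plain-text log; the same config and seed reproduce
the summary byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import GeometryParams, build_network
from .dynamics import DynamicsParams
from .permeability import (C_BASAL_DEFAULT, PEG_547, EpitheliumParams,
                           Molecule, simulate_btj_permeability)
from .ter import ElectricalParams, simulate_ter
from .steady_state import SteadyStateConfig, ss_permeability, ss_resistance
from .presets import get_preset

MODELS = ("permeability", "ter", "steady_state")


@dataclass
class RunConfig:
    """Serializable description of one simulation run."""

    model: str = "permeability"
    preset: str | None = "Caco-2"
    epithelium: dict | None = None        # explicit SI overrides of the preset
    geometry: dict = field(default_factory=dict)
    p_seal: float = 0.033
    mass_da: float = 547.0
    horizon: float | None = None
    replicates: int = 512
    seed: int = 0
    c_basal: float = C_BASAL_DEFAULT
    out: str | None = None

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        if self.preset is None and self.epithelium is None:
            raise ValueError("either a preset name or explicit epithelium "
                             "parameters are required")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    # -- resolution -------------------------------------------------------

    def resolve(self):
        epi = get_preset(self.preset) if self.preset else None
        if self.epithelium:
            base = dataclasses.asdict(epi) if epi else {"name": "custom"}
            base.update(self.epithelium)
            epi = EpitheliumParams(**base)
        geom = GeometryParams(**self.geometry)
        mol = Molecule(self.mass_da)
        return epi, geom, mol


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(type(o))  # pragma: no cover


def run(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute a configured run; returns (and optionally writes) the summary.

    Writes ``summary.json`` (deterministic), ``trace.csv`` and ``run.log``
    into ``out_dir`` (or ``config.out``) when given.
    """
    epi, geom, mol = config.resolve()
    network = build_network(geom)
    summary: dict = {
        "model": config.model,
        "epithelium": epi.name,
        "seed": config.seed,
        "config_hash": config.config_hash(),
    }
    trace_df = None

    if config.model == "permeability":
        dyn = DynamicsParams(epi.p_break, config.p_seal)
        horizon = config.horizon or 7200
        res = simulate_btj_permeability(
            network, dyn, mol, epi, horizon=horizon,
            reps=config.replicates, seed=config.seed, c_basal=config.c_basal)
        summary.update({
            "P_bTJ_nm_s": res.p_btj * 1e9,
            "P_tTJ_nm_s": res.p_ttj * 1e9,
            "P_TJ_nm_s": res.p_tj * 1e9,
            "replicates": res.reps,
            "horizon_s": horizon,
        })
        trace_df = pd.DataFrame({"t_s": res.t,
                                 "q_apical_mean": res.q_apical_mean})
    elif config.model == "ter":
        dyn = DynamicsParams(epi.p_break, config.p_seal)
        elec = ElectricalParams(r_strand=epi.r_strand)
        horizon = config.horizon or 1e5
        res = simulate_ter(network, dyn, elec, epi.l_cb, ttj=epi.ttj,
                           horizon=horizon, seed=config.seed)
        summary.update({
            "TER_ohm_cm2": res.ter_mean * 1e4,
            "R_bTJ_ohm_cm2": res.r_btj_mean * 1e4,
            "R_tTJ_ohm_cm2": res.r_ttj * 1e4,
            "ter_share_ttj": res.share_ttj,
            "horizon_s": horizon,
        })
        trace_df = pd.DataFrame({"t_s": res.t, "TER_ohm_cm2": res.ter * 1e4})
    else:  # steady_state
        dyn = DynamicsParams(epi.p_break, config.p_seal)
        cfg = SteadyStateConfig(network, dyn)
        elec = ElectricalParams(r_strand=epi.r_strand)
        summary.update({
            "model_variant": "steady_state",
            "P_bTJ_ss_nm_s": ss_permeability(cfg, mol, epi.l_cb) * 1e9,
            "R_bTJ_ss_ohm_cm2": ss_resistance(cfg, elec, epi.l_cb) * 1e4,
        })

    out = out_dir or config.out
    if out is not None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True,
                       default=_json_default) + "\n")
        if trace_df is not None:
            trace_df.to_csv(out / "trace.csv", index=False)
        (out / "run.log").write_text(
            f"tjbarrier run\npython {sys.version.split()[0]}\n"
            f"seed {config.seed}\nreplicates {config.replicates}\n"
            f"config_hash {config.config_hash()}\n")
    return summary
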