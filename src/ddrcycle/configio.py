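"""Flat key-value (YAML) parameter files with units in the key names."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .cell_cycle import CellCycleParams
from .pk import PKParams, Regimen, RegimenSpec, build_regimen
from .tumor import TumorParams

# key-in-file -> dataclass field
CYCLE_KEYS = {
    "k1_per_h": "k1", "k2_frac": "k2", "k3_per_h": "k3", "ki_uM": "ki",
    "k4_per_h": "k4", "ks_per_h": "ks", "km_per_h": "km",
    "k_ir_repair_per_h": "k_ir_repair", "k_ir_death_per_h": "k_ir_death",
    "alpha_ir_per_gy": "alpha_ir", "z": "z", "z_ir": "z_ir",
}
PK_KEYS = {
    "ka_per_h": "ka", "cl_l_per_h_kg": "cl", "v1_l_per_kg": "v1",
    "v2_l_per_kg": "v2", "q_l_per_h_kg": "q", "f_frac": "f",
    "mw_conv_um_per_mg_l": "mw_conv", "lag_h": "lag_h",
}
TUMOR_KEYS = {
    "kx_per_h": "kx", "shell_coeff_cells_1_3": "shell_coeff",
    "v_cell_cm3": "v_cell", "v0_cm3": "v0",
}


def _to_config(obj, keymap: dict) -> dict:
    d = asdict(obj)
    return {k: float(d[f]) for k, f in keymap.items()}


def _from_config(cfg: dict, keymap: dict, cls, **extra):
    unknown = set(cfg) - set(keymap)
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    return cls(**{keymap[k]: float(v) for k, v in cfg.items()}, **extra)


def cycle_params_to_config(params: CellCycleParams) -> dict:
    return _to_config(params, CYCLE_KEYS)


def cycle_params_from_config(cfg: dict) -> CellCycleParams:
    return _from_config(cfg, CYCLE_KEYS, CellCycleParams)


def pk_params_to_config(params: PKParams) -> dict:
    return _to_config(params, PK_KEYS)


def pk_params_from_config(cfg: dict) -> PKParams:
    return _from_config(cfg, PK_KEYS, PKParams)


def tumor_params_to_config(params: TumorParams) -> dict:
    out = _to_config(params, TUMOR_KEYS)
    out["cycle"] = cycle_params_to_config(params.cycle)
    return out


def tumor_params_from_config(cfg: dict) -> TumorParams:
    cfg = dict(cfg)
    cycle = cycle_params_from_config(cfg.pop("cycle", {}))
    return _from_config(cfg, TUMOR_KEYS, TumorParams, cycle=cycle)


def regimen_from_config(cfg: dict) -> Regimen:
    """Explicit event lists, or a descriptor under a ``spec`` key."""
    if "spec" in cfg:
        s = cfg["spec"]
        return build_regimen(RegimenSpec(
            drug_dose_mg_kg=float(s.get("drug_dose_mg_kg", 0.0)),
            frequency=s.get("frequency", "QD"),
            drug_days=tuple(s.get("drug_days", ())),
            ir_dose_gy=float(s.get("ir_dose_gy", 0.0)),
            ir_days=tuple(s.get("ir_days", ())),
            ir_lead_h=float(s.get("ir_lead_h", 2.0)),
            bd_interval_h=float(s.get("bd_interval_h", 12.0)),
        ))
    return Regimen(
        drug_doses=tuple(tuple(d) for d in cfg.get("drug_doses", ())),
        ir_fractions=tuple(tuple(d) for d in cfg.get("ir_fractions", ())),
    )


def regimen_to_csv(regimen: Regimen, path) -> None:
    """Write events as rows of event_type (drug|ir), time_h, amount (mg/kg or Gy)."""
    import pandas as pd

    rows = [{"event_type": "drug", "time_h": t, "amount": a}
            for t, a in regimen.drug_doses]
    rows += [{"event_type": "ir", "time_h": t, "amount": d}
             for t, d in regimen.ir_fractions]
    pd.DataFrame(rows, columns=["event_type", "time_h", "amount"]).sort_values(
        ["time_h", "event_type"]).to_csv(path, index=False)


def regimen_from_csv(path) -> Regimen:
    import pandas as pd

    df = pd.read_csv(path)
    missing = {"event_type", "time_h", "amount"} - set(df.columns)
    if missing:
        raise ValueError(f"regimen CSV is missing columns: {sorted(missing)}")
    unknown = set(df["event_type"]) - {"drug", "ir"}
    if unknown:
        raise ValueError(f"unknown event types in regimen CSV: {sorted(unknown)}")
    def events(kind):
        sub = df[df["event_type"] == kind].sort_values("time_h")
        return tuple(zip(sub["time_h"].astype(float), sub["amount"].astype(float)))
    return Regimen(drug_doses=events("drug"), ir_fractions=events("ir"))


def load_yaml(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
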