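"""Data formats and run configuration.

One CSV dialect for titration curves (fixed header, SI-ish units spelled out
in the column names to prevent silent unit drift), a key-value report writer
for fit results, and a YAML run configuration shared by the command-line
subcommands.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constants import AcidConstants, BindingConstants, get_preset
from .fitting import FitResult
from .synthetic import ArtifactModel, TitrationProtocol
from .titration_model import TitrationCurve

__all__ = [
    "TITRATION_COLUMNS",
    "TitrationCsvError",
    "RunConfig",
    "read_titration_csv",
    "write_titration_csv",
    "write_fit_report",
    "load_config",
]

log = logging.getLogger("capspec")

TITRATION_COLUMNS = (
    "replicate",
    "added_ca_mol",
    "free_ca_mol_per_l",
    "ph",
    "volume_l",
    "temperature_k",
)


class TitrationCsvError(ValueError):
    """Malformed titration CSV; carries the offending 1-based data row."""

    def __init__(self, message: str, row: int | None = None):
        if row is not None:
            message = f"{message} (data row {row})"
        super().__init__(message)
        self.row = row


def write_titration_csv(path, curves: list[TitrationCurve]) -> None:
    """Write curves to the standard CSV dialect (decimal point, one header)."""
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "replicate": c.replicate,
                    "added_ca_mol": c.added_ca,
                    "free_ca_mol_per_l": c.free_ca,
                    "ph": c.ph,
                    "volume_l": c.volume,
                    "temperature_k": c.temperature,
                }
            )
        )
    # %.17g guarantees exact binary round-trip of every float
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_titration_csv(path, n_p_total: float = 5.0e-4) -> list[TitrationCurve]:
    """Read titration curves, grouped by (pH, replicate label).

    Strict typing and invariant checks on load; violations are reported with
    the 1-based data row.  ``n_p_total`` (total phosphate, mol) is protocol
    metadata the CSV does not carry.
    """
    try:
        df = pd.read_csv(path, decimal=".", float_precision="round_trip")
    except Exception as exc:
        raise TitrationCsvError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in TITRATION_COLUMNS if c not in df.columns]
    if missing:
        raise TitrationCsvError(f"missing column(s) {missing} in {path}")
    numeric = [c for c in TITRATION_COLUMNS if c != "replicate"]
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(vals.isna().to_numpy())[0]
        if bad.size:
            raise TitrationCsvError(
                f"non-numeric value in column {col!r}", row=int(bad[0]) + 1
            )
        df[col] = vals.astype(float)

    curves = []
    for (ph, rep), sub in df.groupby(["ph", "replicate"], sort=True):
        rows = sub.index.to_numpy() + 1  # 1-based data rows
        added = sub["added_ca_mol"].to_numpy()
        free = sub["free_ca_mol_per_l"].to_numpy()
        vol = sub["volume_l"].to_numpy()
        inc = np.nonzero(np.diff(added) <= 0)[0]
        if inc.size:
            raise TitrationCsvError(
                "added_ca_mol not strictly increasing", row=int(rows[inc[0] + 1])
            )
        over = np.nonzero(free * vol > added * (1 + 1e-9))[0]
        if over.size:
            raise TitrationCsvError(
                "free calcium exceeds the added amount", row=int(rows[over[0]])
            )
        curves.append(
            TitrationCurve(
                added_ca=added,
                free_ca=free,
                volume=vol,
                ph=float(ph),
                temperature=float(sub["temperature_k"].iloc[0]),
                replicate=str(rep),
                n_p_total=n_p_total,
            )
        )
    return curves


def write_fit_report(path, result: FitResult) -> None:
    """Flat key-value fit report plus per-curve RMS residuals."""
    lines = [
        f"model = {result.model}",
        f"k1 = {result.constants.k1:.6g}",
        f"k2 = {result.constants.k2:.6g}",
        f"k3 = {result.constants.k3:.6g}",
        f"temperature_k = {result.constants.temperature:.6g}",
        f"k1_fixed = {result.k1_fixed}",
        f"cost = {result.cost:.6g}",
    ]
    if result.bounds is not None:
        for name, hw, edge in zip(
            ("k1", "k2", "k3"), result.bounds, result.one_sided
        ):
            lines.append(f"{name}_bound = {hw:.6g}")
            lines.append(f"{name}_bound_one_sided = {edge}")
    for label, rms in result.per_curve_rms.items():
        lines.append(f"rms[{label}] = {rms:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated run configuration for the command-line interface."""

    protocol: TitrationProtocol = field(default_factory=TitrationProtocol)
    acid: AcidConstants = field(default_factory=AcidConstants)
    constants: BindingConstants | None = None
    preset: str = "revised"
    artifact: ArtifactModel = field(default_factory=ArtifactModel)
    noise_cv: float = 0.01
    seed: int = 1
    fit_model: str = "predictive"
    fit_tolerance: float = 0.05
    out_dir: str = "."

    def binding_constants(self) -> BindingConstants:
        if self.constants is not None:
            return self.constants
        return get_preset(self.preset, self.protocol.temperature)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Every section is optional; unknown keys are rejected (typo protection),
    and all values pass through the dataclass validators before any
    computation runs.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    known = {"protocol", "acid", "constants", "preset", "artifact",
             "noise_cv", "seed", "fit_model", "fit_tolerance", "out_dir"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")

    def build(cls, key):
        section = raw.get(key)
        if section is None:
            return cls()
        if not isinstance(section, dict):
            raise ValueError(f"config section {key!r} must be a mapping")
        return cls(**section)

    cfg = RunConfig(
        protocol=build(TitrationProtocol, "protocol"),
        acid=build(AcidConstants, "acid"),
        constants=(
            BindingConstants(**raw["constants"]) if raw.get("constants") else None
        ),
        preset=raw.get("preset", "revised"),
        artifact=build(ArtifactModel, "artifact"),
        noise_cv=float(raw.get("noise_cv", 0.01)),
        seed=int(raw.get("seed", 1)),
        fit_model=str(raw.get("fit_model", "predictive")),
        fit_tolerance=float(raw.get("fit_tolerance", 0.05)),
        out_dir=str(raw.get("out_dir", ".")),
    )
    if cfg.fit_model not in ("direct", "predictive"):
        raise ValueError(f"fit_model must be 'direct' or 'predictive'")
    get_preset(cfg.preset)  # resolvable preset name
    log.info("loaded config from %s: %s", path, asdict_compact(cfg))
    return cfg


def asdict_compact(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    return d
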