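"""Delimited-text file formats and study manifests.

All tabular outputs are comma-delimited with a header row; times are in
seconds, concentrations in nM, and rate constants in M^-1 s^-1
(bimolecular) or s^-1 (unimolecular) with an explicit unit column.
Numeric round trips are lossless to better than 12 significant digits.
Structured configuration (manifests, simulate configs) is YAML with a
``format_version`` field.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .kinetics import Trajectory
from .networks import NetworkModel, RateSet, build_network
from .observe import CalibrationCurve, SignalTrace, signal_to_concentration
from .synth import (
    ExperimentDesign,
    NoiseModel,
    StagedStudy,
    Study,
    SyntheticDataset,
    default_calibrations,
    observed_groups,
)
from .observe import observable_weights

__all__ = [
    "FORMAT_VERSION",
    "write_trajectory",
    "read_trajectory",
    "write_signal_trace",
    "read_signal_trace",
    "write_rateset",
    "read_rateset",
    "write_calibration",
    "read_calibration",
    "write_network_listing",
    "write_study",
    "read_study",
]

FORMAT_VERSION = 1
_FLOAT_FMT = "%.17g"  # full double precision; >12 significant digits


# -- trajectories -----------------------------------------------------------

def write_trajectory(traj: Trajectory, path) -> Path:
    """One time column plus one column per species, header row of names."""
    path = Path(path)
    traj.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_trajectory(path, network_kind: str = "") -> Trajectory:
    df = pd.read_csv(path, float_precision="round_trip")
    species = [c for c in df.columns if c != "time_s"]
    return Trajectory(
        df["time_s"].to_numpy(),
        df[species].to_numpy().T,
        species,
        network_kind,
    )


# -- signal traces ----------------------------------------------------------

def write_signal_trace(trace: SignalTrace, path) -> Path:
    path = Path(path)
    pd.DataFrame({
        "well_id": trace.well_id,
        "channel": trace.channel,
        "time_s": trace.times,
        "signal": trace.signal,
    }).to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_signal_trace(path) -> SignalTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    return SignalTrace(
        str(df["well_id"].iloc[0]),
        str(df["channel"].iloc[0]),
        df["time_s"].to_numpy(),
        df["signal"].to_numpy(),
    )


# -- rate sets --------------------------------------------------------------

def _rate_units(rates: RateSet, network: NetworkModel | None) -> dict[str, str]:
    units = {}
    if network is not None:
        for rx in network.reactions:
            units[rx.rate_name] = "M^-1 s^-1" if rx.order == 2 else "s^-1"
    return {n: units.get(n, "") for n in rates.values}


def write_rateset(rates: RateSet, path, network: NetworkModel | None = None) -> Path:
    path = Path(path)
    units = _rate_units(rates, network)
    rows = []
    for name in sorted(rates.values):
        lo, hi = rates.bounds.get(name, (np.nan, np.nan))
        rows.append({
            "rate": name,
            "value": rates.values[name],
            "unit": units[name],
            "status": "unknown" if name in rates.unknown else "known",
            "bound_low": lo,
            "bound_high": hi,
        })
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_rateset(path) -> RateSet:
    df = pd.read_csv(path, float_precision="round_trip")
    values = dict(zip(df["rate"], df["value"].astype(float)))
    unknown = frozenset(df.loc[df["status"] == "unknown", "rate"])
    known = frozenset(values) - unknown
    bounds = {}
    for _, row in df.iterrows():
        lo, hi = row["bound_low"], row["bound_high"]
        if np.isfinite(lo) and np.isfinite(hi):
            bounds[row["rate"]] = (float(lo), float(hi))
    return RateSet(values, known, unknown, bounds)


# -- calibrations -----------------------------------------------------------

def write_calibration(curves: Mapping[str, CalibrationCurve], path) -> Path:
    path = Path(path)
    rows = []
    for channel in sorted(curves):
        cal = curves[channel]
        for sp in sorted(cal.slopes):
            rows.append({"channel": channel, "species": sp,
                         "slope_per_nM": cal.slopes[sp],
                         "background": cal.background})
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_calibration(path) -> dict[str, CalibrationCurve]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = {}
    for channel, grp in df.groupby("channel"):
        out[str(channel)] = CalibrationCurve(
            str(channel),
            dict(zip(grp["species"], grp["slope_per_nM"].astype(float))),
            float(grp["background"].iloc[0]),
        )
    return out


def write_network_listing(network: NetworkModel, path) -> Path:
    """Species and reaction listing as delimited text (two sections)."""
    path = Path(path)
    sp = pd.DataFrame([
        {"species": s.name, "strands": "+".join(s.strands),
         "roles": ";".join(sorted(s.roles))}
        for s in network.species
    ])
    rx = pd.DataFrame([
        {"reactants": "+".join(r.reactants), "products": "+".join(r.products),
         "rate": r.rate_name, "reverse_of": r.reversible_partner or ""}
        for r in network.reactions
    ])
    with open(path, "w") as fh:
        fh.write(f"# network kind: {network.kind}\n# species\n")
        sp.to_csv(fh, index=False)
        fh.write("# reactions\n")
        rx.to_csv(fh, index=False)
    return path


# -- studies ----------------------------------------------------------------

def _design_to_dict(d: ExperimentDesign) -> dict:
    out = dataclasses.asdict(d)
    out["initial"] = {k: float(v) for k, v in d.initial.items()}
    return out


def _design_from_dict(d: Mapping) -> ExperimentDesign:
    return ExperimentDesign(
        d["kind"], dict(d["initial"]), d["trigger_species"],
        float(d["trigger_nM"]), float(d["duration_s"]), float(d["interval_s"]),
        float(d["dead_time_s"]),
    )


def write_study(study: Study | StagedStudy, out_dir) -> Path:
    """Write a synthetic study: manifest plus one file per well and truth.

    Layout: ``manifest.yaml``; ``wells/<label>_<channel>.csv`` signal
    traces; ``truth/<label>.csv`` ground-truth trajectories;
    ``rates/<label>.csv`` the generating rate sets;
    ``calibrations/<kind>.csv`` per network kind.
    """
    out = Path(out_dir)
    for sub in ("wells", "truth", "rates", "calibrations"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    if isinstance(study, StagedStudy):
        roles = [(role, ds) for role in ("binding", "reporter", "recovery",
                                         "discard")
                 for ds in getattr(study, role)]
        meta = {
            "kind": "staged",
            "nominal_monomer": study.nominal_monomer,
            "monomer_scale_true": study.monomer_scale_true,
            "variant": study.variant,
            "seed": study.seed,
            "noise": dataclasses.asdict(study.noise),
        }
    else:
        roles = [("main", ds) for ds in study.datasets]
        meta = {"kind": "study", "preset": study.preset, "seed": study.seed,
                "noise": dataclasses.asdict(study.noise)}

    entries = []
    kinds_written = set()
    for role, ds in roles:
        sig_paths = {}
        for channel, trace in ds.signals.items():
            p = out / "wells" / f"{ds.label}_{channel}.csv"
            write_signal_trace(trace, p)
            sig_paths[channel] = str(p.relative_to(out))
        truth_p = out / "truth" / f"{ds.label}.csv"
        write_trajectory(ds.truth, truth_p)
        rates_p = out / "rates" / f"{ds.label}.csv"
        write_rateset(ds.true_rates, rates_p, ds.network)
        kind = ds.network.kind
        if kind not in kinds_written:
            write_calibration(default_calibrations(ds.network),
                              out / "calibrations" / f"{kind}.csv")
            kinds_written.add(kind)
        entries.append({
            "label": ds.label, "variant": ds.variant, "role": role,
            "network_kind": kind, "design": _design_to_dict(ds.design),
            "seed": int(ds.seed), "signals": sig_paths,
            "truth": str(truth_p.relative_to(out)),
            "rates": str(rates_p.relative_to(out)),
            "calibration": f"calibrations/{kind}.csv",
        })

    manifest = {"format_version": FORMAT_VERSION, **meta, "datasets": entries}
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return out / "manifest.yaml"


def read_study(manifest_path) -> Study | StagedStudy:
    """Load a study written by :func:`write_study` back into memory.

    Signal traces, truth trajectories and rate sets are read from their
    files; converted concentration traces and observable weights are
    rebuilt from the stored calibrations, so a loaded study is directly
    fittable.
    """
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    if manifest.get("format_version") != FORMAT_VERSION:
        raise ValueError(
            f"unsupported format_version {manifest.get('format_version')!r}"
        )

    noise = NoiseModel(**manifest["noise"])
    by_role: dict[str, list[SyntheticDataset]] = {}
    for entry in manifest["datasets"]:
        design = _design_from_dict(entry["design"])
        network = build_network(entry["network_kind"])
        rates = read_rateset(root / entry["rates"])
        truth = read_trajectory(root / entry["truth"], entry["network_kind"])
        calib = read_calibration(root / entry["calibration"])
        groups = observed_groups(entry["network_kind"])
        signals, conc, observables = {}, {}, {}
        for channel, rel in entry["signals"].items():
            trace = read_signal_trace(root / rel)
            signals[channel] = trace
            if channel in groups:
                conc[channel] = signal_to_concentration(
                    trace, calib[channel], groups[channel])
                observables[channel] = observable_weights(
                    calib[channel], groups[channel])
        ds = SyntheticDataset(
            entry["label"], entry["variant"], design, network, rates, truth,
            signals, conc, observables, int(entry["seed"]),
        )
        by_role.setdefault(entry["role"], []).append(ds)

    if manifest["kind"] == "staged":
        return StagedStudy(
            by_role.get("binding", []), by_role.get("reporter", []),
            by_role.get("recovery", []), by_role.get("discard", []),
            float(manifest["nominal_monomer"]),
            float(manifest["monomer_scale_true"]),
            manifest["variant"], int(manifest["seed"]), noise,
        )
    return Study(manifest["preset"], int(manifest["seed"]), noise,
                 by_role.get("main", []))
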