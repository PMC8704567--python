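"""Run configuration, validation, and the two end-to-end workflows.

A run is described by a YAML mapping (or an equivalent dict) with sections:

``field``
    either ``path`` (+ optional ``variable_map``) pointing at a NetCDF file,
    or ``synthetic`` describing a generator (kind: monsoon | uniform |
    downdraft | climatology with that generator's keyword arguments).
``mask``
    ``path`` to a NetCDF land/sea raster; omitted when the synthetic scenario
    provides one.
``flight``
    overrides of :class:`~windborne.flight.FlightParams` fields.
``sites`` / ``arrival_nights``
    trap coordinates (name -> [lon, lat]) and the nights to reconstruct.
``climatology``
    rose levels (hPa), years, months and named sector groups.

Validation is exhaustive: every problem found is reported, not just the first.
Each run writes a manifest (config hash, package version, input checksums)
sufficient to reproduce it, plus a JSON-lines log of every trajectory's
termination reason.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .climatology import (CLIMATOLOGY_SITES, DEFAULT_ROSE_LEVELS_HPA,
                          DEFAULT_PROFILE_LEVELS_HPA, SECTOR_NAMES,
                          downdraft_events, events_to_json, monthly_wind_rose,
                          nightly_level_samples, sector_group_stats,
                          vertical_velocity_profile, EmptyRoseError)
from .flight import FlightParams
from .geography import LandMask
from .inference import filter_and_count, source_region_summary, NoValidLegsError
from .met_field import load_gridded_field
from .synthetic import (make_climatology_field, make_downdraft_field,
                        make_monsoon_scenario, make_uniform_field)
from .trajectory import run_multileg_backward, trajectories_to_frame, legs_to_geojson


class ConfigError(ValueError):
    """Configuration problems; carries the full list of messages."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(self.problems))


class DataError(RuntimeError):
    """Input data inconsistent with the requested run."""


_FLIGHT_FIELDS = {f.name for f in dataclasses.fields(FlightParams)}
_SYNTH_KINDS = ("monsoon", "uniform", "downdraft", "climatology")


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        return dict(path_or_dict)
    with open(path_or_dict) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(["config file must contain a YAML mapping"])
    return cfg


def validate_config(cfg: dict, for_climatology: bool = False) -> list[str]:
    problems = []
    fld = cfg.get("field")
    if not isinstance(fld, dict):
        problems.append("missing 'field' section (path or synthetic)")
    else:
        if ("path" in fld) == ("synthetic" in fld):
            problems.append("'field' needs exactly one of 'path' or 'synthetic'")
        if "path" in fld and not Path(fld["path"]).exists():
            problems.append(f"field path does not exist: {fld['path']}")
        synth = fld.get("synthetic")
        if synth is not None and synth.get("kind") not in _SYNTH_KINDS:
            problems.append(f"synthetic.kind must be one of {_SYNTH_KINDS}")
    mask = cfg.get("mask", {})
    if "path" in mask and not Path(mask["path"]).exists():
        problems.append(f"mask path does not exist: {mask['path']}")
    unknown = set(cfg.get("flight", {})) - _FLIGHT_FIELDS
    if unknown:
        problems.append(f"unknown flight parameter(s): {sorted(unknown)}")
    sites = cfg.get("sites")
    if sites is not None:
        if not isinstance(sites, dict) or not sites:
            problems.append("'sites' must be a non-empty mapping name -> [lon, lat]")
        elif len(set(sites)) != len(sites):
            problems.append("site names must be unique")
    if not for_climatology:
        needs_synth_truth = isinstance(fld, dict) and isinstance(
            fld.get("synthetic"), dict) and fld["synthetic"].get("kind") == "monsoon"
        if not needs_synth_truth:
            if not cfg.get("arrival_nights"):
                problems.append("'arrival_nights' is required for backward inference")
            if not sites:
                problems.append("'sites' is required for backward inference")
            if "path" in (mask or {}) or (isinstance(fld, dict) and "synthetic" in fld):
                pass
            elif "path" not in (mask or {}):
                problems.append("'mask.path' is required when the field is read from file")
    return problems


def _build_field_and_mask(cfg: dict, seed: int):
    """Returns (field, mask, truth-or-None, input checksum map)."""
    fld_cfg = cfg["field"]
    checksums = {}
    truth = None
    if "path" in fld_cfg:
        field = load_gridded_field(fld_cfg["path"], fld_cfg.get("variable_map"))
        checksums[str(fld_cfg["path"])] = _sha256(fld_cfg["path"])
        mask_path = cfg.get("mask", {}).get("path")
        if mask_path is None:
            raise ConfigError(["'mask.path' is required when the field is read from file"])
        mask = LandMask.load(mask_path)
        checksums[str(mask_path)] = _sha256(mask_path)
    else:
        synth = dict(fld_cfg["synthetic"])
        kind = synth.pop("kind")
        synth.setdefault("seed", seed)
        if kind == "monsoon":
            field, truth, mask = make_monsoon_scenario(**synth)
        else:
            maker = {"uniform": make_uniform_field, "downdraft": make_downdraft_field,
                     "climatology": make_climatology_field}[kind]
            if kind in ("uniform", "downdraft"):  # deterministic generators
                synth.pop("seed", None)
            field = maker(**synth)
            mask_path = cfg.get("mask", {}).get("path")
            if mask_path is not None:
                mask = LandMask.load(mask_path)
                checksums[str(mask_path)] = _sha256(mask_path)
            else:
                mask = LandMask.all_sea(field.lats, field.lons)
    return field, mask, truth, checksums


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _flight_params(cfg: dict) -> FlightParams:
    return FlightParams().with_overrides(**cfg.get("flight", {}))


def _write_manifest(outdir: Path, cfg: dict, checksums: dict) -> None:
    canonical = json.dumps(cfg, sort_keys=True, default=str).encode()
    manifest = {
        "config_sha256": hashlib.sha256(canonical).hexdigest(),
        "package_version": __version__,
        "input_checksums": checksums,
        "config": json.loads(json.dumps(cfg, default=str)),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_backward_inference(cfg: dict, output_dir=None) -> dict:
    """Backward source-inference workflow; returns {(site, night): report dict}.

    Writes per-run trajectory CSV and GeoJSON, a validity report JSON, a
    JSON-lines termination log and a reproducibility manifest under the output
    directory.  Deterministic given the config (seed included).
    """
    problems = validate_config(cfg)
    if problems:
        raise ConfigError(problems)
    seed = int(cfg.get("seed", 0))
    params = _flight_params(cfg)
    field, mask, truth, checksums = _build_field_and_mask(cfg, seed)

    sites = cfg.get("sites")
    nights = cfg.get("arrival_nights")
    if truth is not None:
        sites = sites or {"arrival": list(truth.expected_arrival_site)}
        nights = nights or [str(truth.expected_arrival_night)]

    outdir = Path(output_dir or cfg.get("output_dir", "windborne_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    reports = {}
    log_lines = []
    for site_name, (lon, lat) in sites.items():
        for night in nights:
            night64 = np.datetime64(str(night), "D")
            span = field.time_span
            if not (span[0] <= night64.astype("datetime64[s]") <= span[1]):
                raise DataError(
                    f"arrival night {night} outside field span {span[0]} .. {span[1]}")
            paths = run_multileg_backward(lon, lat, night64, field, mask, params)
            report = filter_and_count(paths, mask, params)
            try:
                centroid, hull, degenerate = source_region_summary(paths, mask, params)
                source = {"centroid": [round(c, 6) for c in centroid],
                          "hull_wkt": hull.wkt, "degenerate_hull": degenerate}
            except NoValidLegsError:
                source = None
            tag = f"{site_name}_{night}"
            legs = [leg for p in paths for leg in p.legs]
            trajectories_to_frame(legs).to_csv(outdir / f"trajectories_{tag}.csv",
                                               index=False)
            (outdir / f"trajectories_{tag}.geojson").write_text(
                json.dumps(legs_to_geojson(legs)))
            doc = report.to_dict()
            doc["source_region"] = source
            if truth is not None:
                doc["scenario_truth"] = {
                    "source_centroid": list(truth.source_centroid),
                    "takeoff_time": str(truth.takeoff_time),
                    "leg_count": truth.leg_count,
                }
            (outdir / f"report_{tag}.json").write_text(
                json.dumps(doc, indent=2, sort_keys=True))
            reports[(site_name, str(night))] = doc
            for leg in legs:
                log_lines.append(json.dumps({
                    "site": site_name, "night": str(night),
                    "leg_index": leg.leg_index,
                    "release_time": str(leg.release.time),
                    "altitude_m": leg.release.altitude_m,
                    "termination_reason": leg.termination_reason,
                    "duration_h": round(leg.flight_duration_h, 3)}))
    (outdir / "run_log.jsonl").write_text("\n".join(log_lines) + "\n")
    _write_manifest(outdir, cfg, checksums)
    return reports


def run_climatology(cfg: dict, output_dir=None) -> dict:
    """Climatology workflow: monthly roses, sector-group stats, omega profiles.

    Returns a dict with roses (per month), group statistics and downdraft
    events; writes rose CSVs, an events JSON and profile NetCDFs.
    """
    problems = validate_config(cfg, for_climatology=True)
    if problems:
        raise ConfigError(problems)
    seed = int(cfg.get("seed", 0))
    field, mask, truth, checksums = _build_field_and_mask(cfg, seed)
    clim = cfg.get("climatology", {})
    sites = cfg.get("sites") or CLIMATOLOGY_SITES
    levels = clim.get("levels_hpa", list(DEFAULT_ROSE_LEVELS_HPA))
    years = clim.get("years")
    years = range(years[0], years[1] + 1) if years else range(2010, 2020)
    months = clim.get("months", list(range(1, 13)))
    name_to_idx = {n: i for i, n in enumerate(SECTOR_NAMES)}
    groups = {name: {name_to_idx[s] for s in sectors}
              for name, sectors in clim.get(
                  "groups", {"westerly": ["W"],
                             "pooled_westerly": ["WSW", "W", "WNW"]}).items()}

    outdir = Path(output_dir or cfg.get("output_dir", "windborne_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    samples = nightly_level_samples(field, sites, levels_hpa=levels, years=years,
                                    months=months)
    roses = {}
    for month in months:
        try:
            rose = monthly_wind_rose(samples, month)
        except EmptyRoseError:
            continue
        roses[month] = rose
        rose.to_frame().to_csv(outdir / f"rose_{month:02d}.csv", index=False)
    group_stats = {
        name: {str(m): dict(zip(("frequency_pct", "mean_speed_ms"),
                                sector_group_stats(samples, m, idxs)))
               for m in months}
        for name, idxs in groups.items()}

    events = {}
    for site_name, (lon, lat) in sites.items():
        profile = vertical_velocity_profile(
            field, site_name, lon, lat,
            levels_hpa=clim.get("profile_levels_hpa", DEFAULT_PROFILE_LEVELS_HPA))
        profile.to_dataset().to_netcdf(outdir / f"omega_profile_{site_name}.nc",
                                       engine="scipy")
        events[site_name] = downdraft_events(
            profile, threshold=clim.get("downdraft_threshold", 0.3))
        (outdir / f"downdraft_events_{site_name}.json").write_text(
            events_to_json(events[site_name], indent=2))
    (outdir / "sector_group_stats.json").write_text(
        json.dumps(group_stats, indent=2, sort_keys=True))
    _write_manifest(outdir, cfg, checksums)
    return {"roses": roses, "group_stats": group_stats, "events": events,
            "n_samples": len(samples)}
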