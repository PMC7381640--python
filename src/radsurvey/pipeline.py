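"""Pipeline orchestration: simulate -> unfold -> calibrate -> carborne ->
soil -> assess -> report, as a configured, logged, reproducible run.

A run is driven by a single YAML config in which every survey constant is
inspectable; the completed run writes a ``manifest.json`` capturing the
config hash, seed and package version, and identical config + seed produce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggregate import (
    cumulative_distribution,
    fraction_direct_below,
    grid_minimum_curvature,
    summarize,
    write_esri_ascii,
)
from .carborne import estimate_calibration_by_campaign, reconstruct_dose
from .dosimetry import assess_site
from .hpge import assay_soil, synthetic_efficiency_curve
from .io import read_spe, validate_track_frame, write_spe, write_track_csv
from .spectrometry import (
    analyze_spectrum,
    build_response_matrix,
    calibrate_energy,
    default_binning,
)
from .synthetic import (
    default_truth_config,
    generate_sites,
    linear_route,
    simulate_hpge_spectrum,
    simulate_nai_spectrum,
    simulate_paired_counts,
    simulate_track,
)
from .types import ActivityTriplet, PulseHeightSpectrum, SyntheticSite


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")


@dataclass
class RunConfig:
    """All knobs of a survey run, with the study-condition defaults."""

    outdir: str = "results/run"
    seed: int = 0
    simulate: bool = True
    spectra_dir: str | None = None  # required when simulate is False
    n_sites: int = 462
    n_track_records: int = 1000
    nai_live_time_s: float = 600.0
    paired_live_time_s: float = 30.0
    hpge_live_time_s: float = 30000.0
    soil_mass_kg: float = 0.13
    p_shielded: float | None = None
    builtup_range: tuple[float, float] = (0.5, 2.1)
    dcf: float = 0.14
    cosmic_cps_per_channel: float = 0.01
    grid_spacing_deg: float = 0.25
    grid_mask_radius_cells: int = 3
    write_spectra: bool = False  # SPE files for every site are large; opt in
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "builtup_range" in raw:
            raw["builtup_range"] = tuple(raw["builtup_range"])
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the science-relevant settings (paths and verbosity are
        excluded: they cannot change the computed outputs)."""
        payload = asdict(self)
        for key in ("outdir", "verbosity"):
            payload.pop(key, None)
        canonical = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _log(config: RunConfig, message: str) -> None:
    if config.verbosity > 0:
        print(message, file=sys.stderr)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
        "tables": {},
    }

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            _log(config, f"=== stage {name} ===")
            try:
                result = fn()
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage boundary
                raise PipelineError(name, str(exc)) from exc
            _log(config, f"    done in {time.perf_counter() - t0:.2f} s")
            return result

        return wrap

    truth = default_truth_config(
        seed=config.seed,
        dcf=config.dcf,
        cosmic_cps_per_channel=config.cosmic_cps_per_channel,
    )
    curve = synthetic_efficiency_curve()
    response = build_response_matrix(truth.detector, default_binning())

    # --- simulate ---------------------------------------------------------
    @stage("simulate")
    def simulated():
        if not config.simulate:
            if not config.spectra_dir or not Path(config.spectra_dir).is_dir():
                # surfaced at the unfold stage, which consumes the spectra
                return None
            return None
        rng = np.random.default_rng(config.seed)
        sites = generate_sites(
            truth, config.n_sites,
            p_shielded=config.p_shielded, builtup_range=config.builtup_range,
            rng=rng,
        )
        nai = [
            simulate_nai_spectrum(s, config.nai_live_time_s, truth, rng=rng)
            for s in sites
        ]
        hpge = [
            simulate_hpge_spectrum(
                s.activity, curve, config.hpge_live_time_s, config.soil_mass_kg,
                rng=rng,
            )
            for s in sites
        ]
        paired = simulate_paired_counts(
            sites, truth, config.paired_live_time_s, rng=rng
        )
        tracks = {}
        for region_id, region in truth.regions.items():
            n_pts = max(config.n_track_records // len(truth.regions), 2)
            route = linear_route(
                (region.bbox[0], region.bbox[2]), (region.bbox[1], region.bbox[3]),
                n_pts,
            )
            tracks[region_id] = simulate_track(
                route, [s for s in sites if s.region == region_id], truth,
                campaign=region_id, rng=rng,
            )
        # Energy calibration is performed once per campaign before the
        # measurements (field practice), on a long reference spectrum at the
        # regional mean activity, and reused for every site spectrum.
        energy_cal = {}
        for region_id, region in truth.regions.items():
            ref_site = SyntheticSite(
                site_id=f"cal_{region_id}", region=region_id,
                lat=region.bbox[0], lon=region.bbox[2],
                activity=ActivityTriplet(*region.mean),
                d_air_soil=1.0,
            )
            ref_spectrum = simulate_nai_spectrum(ref_site, 1800.0, truth, rng=rng)
            energy_cal[region_id] = calibrate_energy(ref_spectrum)
        truth_table = pd.DataFrame(
            {
                "site_id": [s.site_id for s in sites],
                "region": [s.region for s in sites],
                "lat": [s.lat for s in sites],
                "lon": [s.lon for s in sites],
                "a_u_true": [s.activity.a_u for s in sites],
                "a_th_true": [s.activity.a_th for s in sites],
                "a_k_true": [s.activity.a_k for s in sites],
                "d_air_soil_true": [s.d_air_soil for s in sites],
                "builtup_factor": [s.builtup_factor for s in sites],
            }
        )
        truth_table.to_csv(outdir / "sites_truth.csv", index=False)
        for region_id, track in tracks.items():
            write_track_csv(track, outdir / f"track_{region_id}.csv")
        if config.write_spectra:
            spec_dir = outdir / "spectra"
            spec_dir.mkdir(exist_ok=True)
            for s, sp in zip(sites, nai):
                write_spe(sp, spec_dir / f"nai_{s.site_id}.spe")
            for s, sp in zip(sites, hpge):
                write_spe(sp, spec_dir / f"hpge_{s.site_id}.spe")
        manifest["tables"]["sites_truth"] = str(outdir / "sites_truth.csv")
        manifest["stages"]["simulate"] = {"n_sites": len(sites)}
        return {
            "sites": sites, "nai": nai, "hpge": hpge,
            "paired": paired, "tracks": tracks, "energy_cal": energy_cal,
        }

    def _require_simulation(stage_name: str):
        if simulated is None:
            raise PipelineError(
                stage_name,
                "stage needs the simulated campaign; with simulate disabled, "
                f"run the '{stage_name}' CLI subcommand on its input files",
            )

    # --- unfold -----------------------------------------------------------
    @stage("unfold")
    def direct_table():
        if simulated is None:
            spectra_dir = Path(config.spectra_dir) if config.spectra_dir else None
            if spectra_dir is None or not spectra_dir.is_dir():
                raise PipelineError(
                    "unfold",
                    f"spectra directory missing or not a directory: {config.spectra_dir!r}",
                )
            rows = []
            for path in sorted(spectra_dir.glob("*.spe")):
                spectrum = read_spe(path)
                res = analyze_spectrum(
                    spectrum, response, recalibrate=not spectrum.is_calibrated
                )
                a = res["activity"]
                rows.append(
                    {
                        "site_id": path.stem, "region": "unassigned",
                        "lat": float("nan"), "lon": float("nan"),
                        "a_u": a.a_u, "a_th": a.a_th, "a_k": a.a_k,
                        "d_air": res["d_air"],
                        "cosmic_cps_per_channel": res["cosmic_cps_per_channel"],
                        "residual": res["residual"],
                    }
                )
            if not rows:
                raise PipelineError("unfold", f"no SPE spectra in {spectra_dir}")
            df = pd.DataFrame(rows)
            df.to_csv(outdir / "direct_activities.csv", index=False)
            manifest["tables"]["direct_activities"] = str(outdir / "direct_activities.csv")
            manifest["stages"]["unfold"] = {"n_spectra": len(df)}
            return df
        rows = []
        for site, spectrum in zip(simulated["sites"], simulated["nai"]):
            offset, gain = simulated["energy_cal"][site.region]
            calibrated = PulseHeightSpectrum(
                spectrum.counts, spectrum.live_time, offset, gain
            )
            res = analyze_spectrum(calibrated, response, recalibrate=False)
            a = res["activity"]
            rows.append(
                {
                    "site_id": site.site_id,
                    "region": site.region,
                    "lat": site.lat,
                    "lon": site.lon,
                    "a_u": a.a_u, "a_th": a.a_th, "a_k": a.a_k,
                    "d_air": res["d_air"],
                    "cosmic_cps_per_channel": res["cosmic_cps_per_channel"],
                    "residual": res["residual"],
                }
            )
        df = pd.DataFrame(rows)
        df.to_csv(outdir / "direct_activities.csv", index=False)
        manifest["tables"]["direct_activities"] = str(outdir / "direct_activities.csv")
        manifest["stages"]["unfold"] = {"n_spectra": len(df)}
        return df

    # --- calibrate --------------------------------------------------------
    @stage("calibrate")
    def calibrations():
        _require_simulation("calibrate")
        paired = simulated["paired"].merge(
            direct_table[["site_id", "d_air"]], on="site_id"
        )
        calibs = estimate_calibration_by_campaign(paired)
        payload = {
            campaign: {
                "sf_carbody": c.sf_carbody, "u_sf_carbody": c.u_sf_carbody,
                "sf_asphalt": c.sf_asphalt, "u_sf_asphalt": c.u_sf_asphalt,
                "dcf": c.dcf, "u_dcf": c.u_dcf,
                "n": c.n_carbody,
            }
            for campaign, c in calibs.items()
        }
        with open(outdir / "calibration.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        manifest["tables"]["calibration"] = str(outdir / "calibration.json")
        manifest["stages"]["calibrate"] = {"campaigns": sorted(calibs)}
        return calibs

    # --- carborne ---------------------------------------------------------
    @stage("carborne")
    def track_doses():
        _require_simulation("carborne")
        frames = []
        for region_id, track in simulated["tracks"].items():
            dosed = reconstruct_dose(track, calibrations)
            frames.append(dosed.records)
        df = pd.concat(frames, ignore_index=True)
        df.to_csv(outdir / "track_dose.csv", index=False)
        manifest["tables"]["track_dose"] = str(outdir / "track_dose.csv")
        manifest["stages"]["carborne"] = {"n_records": len(df)}
        return df

    # --- soil -------------------------------------------------------------
    @stage("soil")
    def soil_table():
        _require_simulation("soil")
        rows = []
        for site, spectrum in zip(simulated["sites"], simulated["hpge"]):
            a = assay_soil(spectrum, curve, config.soil_mass_kg)
            rows.append(
                {
                    "site_id": site.site_id, "region": site.region,
                    "a_u": a.a_u, "a_th": a.a_th, "a_k": a.a_k,
                    "u_u": a.u_u, "u_th": a.u_th, "u_k": a.u_k,
                }
            )
        df = pd.DataFrame(rows)
        df.to_csv(outdir / "soil_activities.csv", index=False)
        manifest["tables"]["soil_activities"] = str(outdir / "soil_activities.csv")
        manifest["stages"]["soil"] = {"n_samples": len(df)}
        return df

    # --- assess -----------------------------------------------------------
    @stage("assess")
    def assessment():
        merged = direct_table.merge(
            soil_table, on=["site_id", "region"], suffixes=("_direct", "_soil")
        )
        rows = []
        for _, r in merged.iterrows():
            soil_triplet = ActivityTriplet(r["a_u_soil"], r["a_th_soil"], r["a_k_soil"])
            direct_triplet = ActivityTriplet(
                r["a_u_direct"], r["a_th_direct"], r["a_k_direct"]
            )
            a_soil = assess_site(
                activity=soil_triplet, site_id=r["site_id"], region=r["region"]
            )
            a_direct = assess_site(
                activity=direct_triplet,
                d_air_direct=r["d_air"],
                d_air_soil=a_soil.d_air_soil,
                site_id=r["site_id"],
                region=r["region"],
            )
            rows.append(
                {
                    "site_id": r["site_id"], "region": r["region"],
                    "d_air_direct": a_direct.d_air_direct,
                    "d_air_soil": a_soil.d_air_soil,
                    "oaed_direct": a_direct.oaed, "iaed_direct": a_direct.iaed,
                    "total_aed_direct": a_direct.total_aed,
                    "oaed_soil": a_soil.oaed, "iaed_soil": a_soil.iaed,
                    "total_aed_soil": a_soil.total_aed,
                    "ra_eq_direct": a_direct.ra_eq, "ra_eq_soil": a_soil.ra_eq,
                    "h_ex_direct": a_direct.h_ex, "h_ex_soil": a_soil.h_ex,
                    "exceeds_limit_direct": a_direct.exceeds_limit,
                    "exceeds_limit_soil": a_soil.exceeds_limit,
                    "ratio_of_difference": a_direct.ratio_of_difference,
                }
            )
        df = pd.DataFrame(rows)
        df.to_csv(outdir / "assessment.csv", index=False)
        manifest["tables"]["assessment"] = str(outdir / "assessment.csv")
        manifest["stages"]["assess"] = {"n_sites": len(df)}
        return df

    # --- report -----------------------------------------------------------
    @stage("report")
    def report():
        tables = {}
        for col in (
            "d_air_direct", "d_air_soil", "total_aed_direct", "total_aed_soil",
            "h_ex_direct", "h_ex_soil", "ratio_of_difference",
        ):
            tables[f"summary_{col}"] = summarize(assessment, col)
        summary = pd.concat(
            tables, names=["quantity", "row"]
        ).reset_index(level=0)
        summary.to_csv(outdir / "summary_regional.csv", index=False)

        hx_d, frac_d = cumulative_distribution(assessment["h_ex_direct"])
        hx_s, frac_s = cumulative_distribution(assessment["h_ex_soil"])
        cdf = pd.DataFrame(
            {
                "h_ex_direct": hx_d, "cumfrac_direct": frac_d,
                "h_ex_soil": hx_s, "cumfrac_soil": frac_s,
            }
        )
        cdf.to_csv(outdir / "h_ex_cdf.csv", index=False)
        frac_below = fraction_direct_below(
            assessment["h_ex_direct"], assessment["h_ex_soil"]
        )

        grid = grid_minimum_curvature(
            track_doses, spacing=config.grid_spacing_deg,
            mask_radius_cells=config.grid_mask_radius_cells,
        )
        write_esri_ascii(grid, outdir / "dose_grid.asc")

        manifest["tables"]["summary_regional"] = str(outdir / "summary_regional.csv")
        manifest["tables"]["h_ex_cdf"] = str(outdir / "h_ex_cdf.csv")
        manifest["tables"]["dose_grid"] = str(outdir / "dose_grid.asc")
        manifest["stages"]["report"] = {
            "fraction_h_ex_direct_below_soil": frac_below,
            "mean_ratio_of_difference": float(
                assessment["ratio_of_difference"].mean()
            ),
            "mean_total_aed_soil": float(assessment["total_aed_soil"].mean()),
            "mean_total_aed_direct": float(assessment["total_aed_direct"].mean()),
        }
        return tables

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def validate_inputs(paths: dict) -> dict:
    """Report-only validation of input files.

    ``paths`` maps kinds ("track", "spectrum") to file paths; returns
    {"errors": [...], "warnings": [...]}.
    """
    errors: list[str] = []
    warnings_list: list[str] = []
    for kind, path in paths.items():
        p = Path(path)
        if not p.exists():
            errors.append(f"{kind}: file not found: {path}")
            continue
        if kind.startswith("track"):
            try:
                df = pd.read_csv(p)
            except Exception as exc:  # noqa: BLE001
                errors.append(f"{kind}: unreadable CSV ({exc})")
                continue
            errors.extend(validate_track_frame(df, name=str(path)))
        elif kind.startswith("spectrum"):
            try:
                spectrum = read_spe(p)
            except ValueError as exc:
                errors.append(f"{kind}: {exc}")
                continue
            if not spectrum.is_calibrated:
                warnings_list.append(f"{kind}: spectrum lacks an energy calibration")
        else:
            warnings_list.append(f"{kind}: unknown input kind, skipped")
    return {"errors": errors, "warnings": warnings_list}
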