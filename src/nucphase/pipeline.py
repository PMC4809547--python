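"""End-to-end orchestration: cohort helpers and the config-driven pipeline.

``run_synthetic_cohort`` chains the full analysis on generated data
(simulate sites and fragments -> midpoints -> aggregate -> normalize ->
smooth -> peak detection -> phasing summary) and is the entry point used by
the acceptance workflow. ``run_pipeline`` executes the same stages from a
YAML configuration over synthetic scenarios or on-disk files and writes a
manifest that records every parameter, seed, count and the digestion-match
verdict, so any stage can be re-run in isolation with identical results.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from . import __version__
from .coregulation import coregulation_analysis
from .fragments import LengthStats, digestion_match, fragment_midpoints, length_stats
from .io import (
    FragmentRecord,
    SiteRecord,
    read_de_table,
    read_fragments,
    read_sites,
    write_profile,
    write_sites,
)
from .phasing import (
    PhasingSummary,
    compare_conditions,
    detect_peaks,
    summarize_phasing,
)
from .profile import DyadProfile, aggregate, normalize, smooth
from .simulate import (
    ScenarioSpec,
    scenario_presets,
    simulate_fragments,
    simulate_sites,
)
from .sites import filter_by_proximity, site_anchor

__all__ = [
    "CohortResult",
    "profile_from_fragments",
    "run_synthetic_cohort",
    "run_pipeline",
]

DEFAULT_PARAMS: dict[str, Any] = {
    "half_window": 1000,
    "smooth_bp": 50,
    "ctcf_radius": 500,
    "length_tolerance": 5.0,
    "max_fragment_length": 500,
    "prominence_frac": 0.25,
    "min_separation": 120,
    "max_peaks_per_side": 10,
    "center_halfwidth": 73,
    "fc_threshold": 1.5,
    "p_max": 0.05,
    "q_max": 0.05,
    "n_sites": 2000,
    "chrom_length": 10_000_000,
    "min_gap": 3000,
}


@dataclass(frozen=True)
class CohortResult:
    """Everything the pipeline derives from one condition's fragments."""

    profile: DyadProfile
    summary: PhasingSummary
    lengths: LengthStats
    n_fragments: int


def profile_from_fragments(
    fragments: Sequence[FragmentRecord],
    sites: Sequence[SiteRecord],
    half_window: int = 1000,
    smooth_bp: int = 50,
    use_summit: bool = False,
    flip_by_strand: bool = False,
) -> DyadProfile:
    """Aggregate fragment midpoints around site anchors into a smoothed profile."""
    anchors = [site_anchor(s, use_summit, flip_by_strand) for s in sites]
    raw = aggregate(fragment_midpoints(fragments), anchors, half_window)
    prof = normalize(raw)
    if smooth_bp:
        prof = smooth(prof, smooth_bp)
    return prof


def run_synthetic_cohort(
    scenario: ScenarioSpec,
    n_sites: int = 2000,
    seed: int | None = None,
    half_window: int = 1000,
    smooth_bp: int = 50,
    chrom_length: int = 10_000_000,
    min_gap: int = 3000,
    prominence_frac: float = 0.25,
    min_separation: int = 120,
    max_peaks_per_side: int = 10,
) -> CohortResult:
    """Simulate one cohort and run the full phasing pipeline on it.

    ``seed`` (defaulting to the scenario's own) seeds both site placement
    and fragment sampling, so paired conditions run with the same seed share
    their site coordinates and differ only in the scenario parameters.
    """
    if seed is None:
        seed = scenario.seed
    else:
        scenario = dataclasses.replace(scenario, seed=seed)
    sites = simulate_sites(n_sites, chrom_length, min_gap, seed)
    frags, _ = simulate_fragments(sites, scenario)
    prof = profile_from_fragments(frags, sites, half_window, smooth_bp)
    peaks = detect_peaks(prof, prominence_frac, min_separation)
    summary = summarize_phasing(prof, peaks, max_peaks_per_side)
    return CohortResult(
        profile=prof,
        summary=summary,
        lengths=length_stats(frags),
        n_fragments=len(frags),
    )


def _summary_dict(s: PhasingSummary) -> dict[str, Any]:
    return {
        "plus_one": s.plus_one,
        "minus_one": s.minus_one,
        "p1m1_distance": s.p1m1_distance,
        "nrl_left": s.nrl_left,
        "nrl_right": s.nrl_right,
        "nrl": s.nrl,
        "n_peaks_used_per_side": list(s.n_peaks_used_per_side),
        "amplitude": s.amplitude,
    }


def _load_condition(
    name: str, cond: Mapping[str, Any], sites: Sequence[SiteRecord], params: Mapping[str, Any], seed: int
) -> tuple[Sequence[FragmentRecord], int]:
    if "scenario" in cond:
        presets = scenario_presets()
        scen = presets[cond["scenario"]]
        scen = dataclasses.replace(scen, seed=seed)
        if "overhang_mean" in cond:  # per-condition digestion extent
            scen = dataclasses.replace(
                scen,
                digestion=dataclasses.replace(
                    scen.digestion, overhang_mean=float(cond["overhang_mean"])
                ),
            )
        return simulate_fragments(sites, scen)
    frags, dropped = read_fragments(
        cond["fragments"],
        cond.get("format", "bedpe"),
        params["max_fragment_length"],
    )
    return frags, dropped


def run_pipeline(config: Mapping[str, Any] | str | Path, output_dir: str | Path | None = None) -> dict:
    """Run the full pipeline from a configuration mapping or YAML file.

    Config keys: ``output_dir``; ``conditions`` (mapping of condition name
    to either ``{scenario: <preset name>}`` or ``{fragments: <path>}``);
    optional ``sites`` (path; generated when absent and any condition is
    synthetic), ``exclude_near`` (reference-site path for the proximity
    filter), ``seed``, ``params`` (overrides of :data:`DEFAULT_PARAMS`),
    ``compare`` (list of ``[control, experimental]`` name pairs) and
    ``coregulation`` (``{table_a: path, table_b: path}``). Returns the
    manifest, which is also written as ``manifest.json``. The manifest is a
    pure function of the config, so repeated runs are byte-identical.
    """
    if not isinstance(config, Mapping):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if "conditions" not in config or not config["conditions"]:
        raise ValueError("config must define at least one condition")
    params = dict(DEFAULT_PARAMS)
    params.update(config.get("params", {}))
    seed = int(config.get("seed", 0))
    out_dir = Path(output_dir or config["output_dir"])

    # fail on missing inputs before any stage runs
    file_keys: list[str] = []
    for name, cond in config["conditions"].items():
        if "scenario" not in cond:
            if "fragments" not in cond:
                raise ValueError(f"condition {name!r} needs 'scenario' or 'fragments'")
            file_keys.append(cond["fragments"])
    for key in ("sites", "exclude_near"):
        if config.get(key):
            file_keys.append(config[key])
    for key in ("table_a", "table_b"):
        if config.get("coregulation", {}).get(key):
            file_keys.append(config["coregulation"][key])
    missing = [f for f in file_keys if not Path(f).exists()]
    if missing:
        raise FileNotFoundError(f"missing input files: {missing}")

    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "profiles").mkdir(exist_ok=True)
    (out_dir / "summaries").mkdir(exist_ok=True)

    manifest: dict[str, Any] = {
        "nucphase_version": __version__,
        "seed": seed,
        "params": params,
        "conditions": {},
        "comparisons": {},
    }

    # sites: from file or synthetic
    if config.get("sites"):
        sites = read_sites(config["sites"], config.get("sites_format", "bed6"))
        manifest["sites"] = {"path": str(config["sites"]), "n": len(sites)}
    else:
        sites = simulate_sites(
            params["n_sites"], params["chrom_length"], params["min_gap"], seed
        )
        write_sites(sites, out_dir / "sites.bed")
        manifest["sites"] = {"synthetic": True, "n": len(sites)}

    if config.get("exclude_near"):
        refs = read_sites(config["exclude_near"], config.get("exclude_format", "bed6"))
        res = filter_by_proximity(sites, refs, params["ctcf_radius"])
        sites = res.retained
        manifest["site_filter"] = {
            "reference": str(config["exclude_near"]),
            "radius": params["ctcf_radius"],
            "retained": len(res.retained),
            "excluded": len(res.excluded),
            "excluded_fraction": res.excluded_fraction,
        }
        if not sites:
            raise ValueError("proximity filter excluded every site")

    stats: dict[str, LengthStats] = {}
    results: dict[str, CohortResult] = {}
    for name, cond in config["conditions"].items():
        frags, dropped_or_clipped = _load_condition(name, cond, sites, params, seed)
        ls = length_stats(frags)
        prof = profile_from_fragments(
            frags, sites, params["half_window"], params["smooth_bp"]
        )
        peaks = detect_peaks(prof, params["prominence_frac"], params["min_separation"])
        summary = summarize_phasing(prof, peaks, params["max_peaks_per_side"])
        write_profile(prof, out_dir / "profiles" / f"{name}.tsv")
        with open(out_dir / "summaries" / f"{name}.json", "w") as fh:
            json.dump(_summary_dict(summary), fh, indent=2, sort_keys=True)
        stats[name] = ls
        results[name] = CohortResult(prof, summary, ls, len(frags))
        manifest["conditions"][name] = {
            "source": cond.get("scenario") or str(cond.get("fragments")),
            "n_fragments": len(frags),
            "dropped_or_clipped": dropped_or_clipped,
            "mean_fragment_length": ls.mean_length,
        }

    names = list(config["conditions"])
    pairs = config.get("compare")
    if pairs is None and len(names) > 1:
        pairs = [[names[0], other] for other in names[1:]]
    for ctrl, expt in pairs or []:
        verdict = digestion_match(stats[ctrl], stats[expt], params["length_tolerance"])
        entry: dict[str, Any] = {
            "digestion_mismatch": not verdict.matched,
            "delta_mean_length": verdict.delta_mean,
        }
        c, e = results[ctrl], results[expt]
        try:
            delta = compare_conditions(
                c.summary,
                c.profile,
                e.summary,
                e.profile,
                digestion_matched=verdict.matched,
                center_halfwidth=params["center_halfwidth"],
            )
            entry.update(
                delta_p1m1=delta.delta_p1m1,
                delta_nrl=delta.delta_nrl,
                delta_center_occupancy=delta.delta_center_occupancy,
            )
        except ValueError as exc:
            entry["comparison_error"] = str(exc)
        manifest["comparisons"][f"{ctrl}_vs_{expt}"] = entry
        with open(out_dir / "summaries" / f"delta_{ctrl}_vs_{expt}.json", "w") as fh:
            json.dump(entry, fh, indent=2, sort_keys=True)

    if config.get("coregulation"):
        cfg = config["coregulation"]
        res = coregulation_analysis(
            read_de_table(cfg["table_a"]),
            read_de_table(cfg["table_b"]),
            params["fc_threshold"],
            params["p_max"],
            params["q_max"],
        )
        manifest["coregulation"] = dataclasses.asdict(res)
        with open(out_dir / "summaries" / "coregulation.json", "w") as fh:
            json.dump(dataclasses.asdict(res), fh, indent=2, sort_keys=True)

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
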