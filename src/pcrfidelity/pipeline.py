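"""Pipeline orchestration: simulate -> filter -> rates / inversions /
recombination, driven by a YAML config, with machine-readable reports and a
run manifest.

Reports are deterministic byte-for-byte under a fixed config+seed: JSON is
written with sorted keys and no timestamps (the manifest alone carries a
timestamp, outside the hashed report set).
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .exceptions import ConfigError
from .filtering import RATES_POLICY, SWITCHING_POLICY, FilterPolicy, filter_reads
from .inversions import (build_inversion_references, inversion_rates,
                         scan_reads)
from .rates import (count_errors, mutational_spectrum, round_sig,
                    summarize_rates)
from .recombination import analyze_reads
from .reads import emit_reads
from .simulate import (SimulationConfig, product_references,
                       simulate_amplification)
from .templates import (AmpliconSpec, InvertedRepeatElement, TemplateEntry,
                        TemplateSet, insert_inverted_repeat,
                        make_artificial_template)
from .dna import random_sequence
import numpy as np

_TEMPLATE_KINDS = ("amplicon", "homolog-pair", "structured")

DEFAULTS = {
    "templates": {"kind": "amplicon", "length": 1100, "marker_count": 9,
                  "elements": [], "template_seed_offset": 1000003},
    "simulation": {},
    "filters": {"rates": {}, "switching": {"min_passes": 3,
                                           "require_max_event_qv": False,
                                           "require_mapq": 0,
                                           "min_length_fraction": 0.0,
                                           "drop_chimeric": False}},
    "report": {"yield": None, "input": None, "cycles": None},
}


def validate_config(source) -> dict:
    """Parse, validate and normalize a pipeline config.

    ``source`` is a path to a YAML file or an already-parsed mapping.
    Raises :class:`ConfigError` listing every violated field; returns the
    normalized config with defaults injected.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ConfigError([("", "config must be a mapping")])
    problems = []
    cfg = {}
    for section, defaults in DEFAULTS.items():
        merged = dict(defaults)
        merged.update(raw.get(section) or {})
        cfg[section] = merged
    if "seed" not in raw or raw["seed"] is None:
        problems.append(("seed", "a seed is mandatory for reproducibility"))
    else:
        cfg["seed"] = int(raw["seed"])
    if cfg["templates"]["kind"] not in _TEMPLATE_KINDS:
        problems.append(("templates.kind",
                         f"must be one of {_TEMPLATE_KINDS}"))
    sim = dict(cfg["simulation"])
    sim.setdefault("seed", cfg.get("seed", 0))
    if "target_doublings" not in sim and "efficiency_per_cycle" not in sim:
        sim["target_doublings"] = 10.0
    try:
        cfg["simulation_config"] = SimulationConfig(**sim)
    except ConfigError as exc:
        problems.extend(("simulation." + p, r) for p, r in exc.problems)
    except TypeError as exc:
        problems.append(("simulation", str(exc)))
    for name in ("rates", "switching"):
        try:
            cfg[f"{name}_policy"] = FilterPolicy(**cfg["filters"][name])
        except (TypeError, ValueError) as exc:
            problems.append((f"filters.{name}", str(exc)))
    if problems:
        raise ConfigError(problems)
    return cfg


def build_templates(cfg: dict) -> TemplateSet:
    """Construct the template set described by the config."""
    tc = cfg["templates"]
    seed = cfg["seed"] + tc["template_seed_offset"]
    rng = np.random.default_rng(seed)
    if tc["kind"] == "homolog-pair":
        seq_a, seq_b, table = make_artificial_template(
            tc["length"], tc["marker_count"], rng)
        return TemplateSet(
            entries=[TemplateEntry("DNA-A", seq_a, "homolog-A"),
                     TemplateEntry("DNA-B", seq_b, "homolog-B")],
            marker_table=table)
    if tc["kind"] == "structured":
        seq = random_sequence(tc["length"], rng)
        elements = []
        for spec in tc["elements"]:
            seq, el = insert_inverted_repeat(
                seq, spec["start"], spec["stem_length"], spec["loop_length"],
                rng)
            elements.append(el)
        return TemplateSet(
            entries=[TemplateEntry("structured-1", seq, "structured")],
            elements=elements)
    seq = random_sequence(tc["length"], rng)
    return TemplateSet(entries=[TemplateEntry("amplicon-1", seq, "amplicon")])


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def config_hash(cfg: dict) -> str:
    canon = {k: v for k, v in cfg.items()
             if k in ("seed", "templates", "simulation", "filters", "report")}
    blob = json.dumps(canon, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def run_fidelity(config, outdir, seed: int | None = None) -> dict:
    """Run the full pipeline; returns the manifest dictionary.

    ``config`` is a path or mapping accepted by :func:`validate_config`;
    ``seed`` overrides the config seed when given.
    """
    cfg = validate_config(config)
    if seed is not None:
        raw = {k: cfg[k] for k in
               ("templates", "simulation", "filters", "report")}
        raw["seed"] = seed
        cfg = validate_config(raw)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    templates = build_templates(cfg)
    sim_cfg = cfg["simulation_config"]
    reads, truth = simulate_amplification(templates, sim_cfg)
    n_doublings = simulate_amplification.last_doublings
    refs = product_references(templates)
    emit_reads(reads, truth, refs, outdir / "sim")

    stage_counts = {"simulated_reads": len(reads)}
    report_cfg = cfg["report"]
    n_for_norm = n_doublings
    if report_cfg["yield"] is not None and report_cfg["input"] is not None:
        from .rates import doublings_from_yield
        n_for_norm = doublings_from_yield(report_cfg["yield"],
                                          report_cfg["input"])

    # --- error rates (strict policy) ------------------------------------
    rate_reads, audit = filter_reads(reads, cfg["rates_policy"])
    stage_counts["rate_reads"] = len(rate_reads)
    base_names = set(templates.references())
    rate_reads = [r for r in rate_reads if r.reference_name in base_names]
    masked_sites = None
    if templates.marker_table is not None:
        sites = set(templates.marker_table.positions0())
        masked_sites = {name: sites for name in base_names}
    counts, _ = count_errors(rate_reads, templates.references(),
                             cfg["rates_policy"], masked_sites=masked_sites,
                             audit=audit)
    summary = summarize_rates(counts, n=n_for_norm,
                              cycles=report_cfg["cycles"])
    rates_report = {k: (round_sig(v, 6) if isinstance(v, float) else v)
                    for k, v in summary.as_dict().items()}
    _write_json({"rates": rates_report, "audit": audit.as_dict()},
                outdir / "rates.json")
    pd.DataFrame([summary.as_dict()]).to_csv(outdir / "rates.tsv",
                                             sep="\t", index=False)
    try:
        spectrum = mutational_spectrum(counts)
        _write_json(spectrum.as_dict(), outdir / "spectrum.json")
        pd.DataFrame(sorted(spectrum.as_dict().items()),
                     columns=["pair", "percent"]).to_csv(
            outdir / "spectrum.tsv", sep="\t", index=False)
    except Exception:
        spectrum = None

    # --- inversion scan --------------------------------------------------
    switching_reads, _ = filter_reads(reads, cfg["switching_policy"])
    inversion_report = {}
    carrier = templates.get_by_role("structured") or templates.entries
    for idx, element in enumerate(templates.elements):
        quad = build_inversion_references(carrier[0].sequence, element)
        calls = scan_reads(switching_reads, quad,
                           min_passes=cfg["switching_policy"].min_passes)
        inversion_report[f"element_{idx}"] = inversion_rates(calls)
    if inversion_report:
        _write_json(inversion_report, outdir / "inversions.json")
        rows = [{"element": k, "class": lab, "percent": v["per_class_pct"][lab]}
                for k, v in inversion_report.items()
                for lab in v["per_class_pct"]]
        pd.DataFrame(rows).to_csv(outdir / "inversions.tsv", sep="\t",
                                  index=False)

    # --- recombination scan ----------------------------------------------
    recomb_report = None
    pair = templates.homolog_pair()
    if pair is not None and templates.marker_table is not None:
        scan = [r for r in switching_reads
                if r.reference_name in (pair[0].name, pair[1].name)]
        result, _vectors = analyze_reads(scan, pair[0].sequence,
                                         templates.marker_table,
                                         n=n_for_norm)
        recomb_report = result.as_dict()
        _write_json(recomb_report, outdir / "recombination.json")
        pd.DataFrame([recomb_report]).to_csv(outdir / "recombination.tsv",
                                             sep="\t", index=False)

    manifest = {
        "package_version": __version__,
        "config_hash": config_hash(cfg),
        "seed": cfg["seed"],
        "n_doublings": n_for_norm,
        "stage_counts": stage_counts,
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    _write_json(manifest, outdir / "manifest.json")
    return manifest
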