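"""End-to-end orchestration: simulate -> consensus -> matrices -> classify ->
annotate -> proximity -> signature (-> PCA), with a run manifest.

A single YAML/dict configuration drives every stage; all randomness flows
from one top-level seed, split per stage by the generator's documented
scheme. The manifest records the tool version, a hash of the resolved
configuration, the seed, and a SHA-256 digest of every output file, so a
re-run with identical config and seed is verifiably identical
(timestamps aside).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import center_distance_stats, expression_signature, nearest_tss
from .classify import (
    AccessibilityProfile,
    accessibility_scalars,
    accessibility_threshold,
    chi_square_accessibility,
    classify_types,
    contingency_from_calls,
    enhancer_categories,
    enhancer_retention,
    pca_samples,
)
from .consensus import ConsensusConfig, consensus_sites
from .intervals import IntervalIndex, PeakSet, write_bed
from .signal import (
    bimodality_index,
    metagene_profile,
    normalize_per_million,
    signal_matrix,
)
from .simulate import (
    SimulationConfig,
    simulate_accessibility_panel,
    simulate_expression,
    simulate_peak_replicates,
    simulate_tracks,
    simulate_truth,
)

__all__ = ["PipelineConfigError", "RunManifest", "load_config", "run_pipeline"]


class PipelineConfigError(ValueError):
    """Configuration fails validation before any stage runs."""


_SECTION_DEFAULTS: dict[str, dict[str, Any]] = {
    "simulate": {},  # any SimulationConfig field
    "consensus": {"min_treatment_support": 2},
    "matrix": {"window": 1500, "bin_size": 50},
    "classify": {
        "k": 2,
        "persistence_threshold": 0.5,
        "accessibility_quantile": 0.75,
        "accessibility_min_fold": 10.0,
        "n_background": 1000,
    },
    "annotate": {"promoter_bp": 1000, "distal_bp": 5000},
    "proximity": {"max_distance": 2000},
    "signature": {"fold_threshold": 2.0, "sc_expressed_min": 1.0},
    "pca": {"enabled": True, "n_background_sites": 2000},
}


@dataclass
class RunManifest:
    version: str
    seed: int
    config_hash: str
    started: str
    finished: str = ""
    outputs: dict[str, list[str]] = field(default_factory=dict)
    digests: dict[str, str] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")


def load_config(path: str | Path) -> dict:
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise PipelineConfigError("config root must be a mapping")
    return cfg


def _resolve_config(config: dict, seed: int | None) -> dict:
    """Merge defaults, validate field names and cross-field constraints."""
    known = set(_SECTION_DEFAULTS) | {"seed"}
    unknown = set(config) - known
    if unknown:
        raise PipelineConfigError(f"unknown config sections: {sorted(unknown)}")
    resolved: dict[str, Any] = {"seed": int(config.get("seed", 0))}
    if seed is not None:
        resolved["seed"] = int(seed)
    for section, defaults in _SECTION_DEFAULTS.items():
        given = config.get(section) or {}
        if not isinstance(given, dict):
            raise PipelineConfigError(f"section {section!r} must be a mapping")
        if section == "simulate":
            valid = set(SimulationConfig.__dataclass_fields__) - {"seed"}
            bad = set(given) - valid
            if bad:
                raise PipelineConfigError(
                    f"unknown simulate fields: {sorted(bad)}"
                )
            resolved[section] = dict(given)
        else:
            bad = set(given) - set(defaults)
            if bad:
                raise PipelineConfigError(
                    f"unknown fields in section {section!r}: {sorted(bad)}"
                )
            resolved[section] = {**defaults, **given}
    try:
        sim = SimulationConfig(seed=resolved["seed"], **resolved["simulate"])
    except (TypeError, ValueError) as exc:
        raise PipelineConfigError(f"invalid simulate section: {exc}") from None
    if resolved["consensus"]["min_treatment_support"] > sim.n_treatment_reps:
        raise PipelineConfigError(
            "consensus.min_treatment_support exceeds the number of "
            "treatment replicates"
        )
    if resolved["matrix"]["window"] % resolved["matrix"]["bin_size"] != 0:
        raise PipelineConfigError("matrix.window must be divisible by bin_size")
    return resolved


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: dict | str | Path, outdir: str | Path, seed: int | None = None
) -> RunManifest:
    """Execute every stage on a simulated study and write all outputs.

    ``config`` is a mapping (or path to a YAML file) with optional sections
    ``simulate``, ``consensus``, ``matrix``, ``classify``, ``annotate``,
    ``proximity``, ``signature``, ``pca`` and a top-level ``seed``
    (overridable by the ``seed`` argument). Raises
    :class:`PipelineConfigError` before any stage runs if validation fails.
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    resolved = _resolve_config(config, seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    canonical = json.dumps(resolved, sort_keys=True).encode()
    manifest = RunManifest(
        version=__version__,
        seed=resolved["seed"],
        config_hash=hashlib.sha256(canonical).hexdigest(),
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    summary: dict[str, Any] = {"seed": resolved["seed"]}

    def record(stage: str, path: Path) -> None:
        manifest.outputs.setdefault(stage, []).append(path.name)
        manifest.digests[path.name] = _sha256(path)

    # -- simulate ----------------------------------------------------------
    sim_cfg = SimulationConfig(seed=resolved["seed"], **resolved["simulate"])
    truth = simulate_truth(sim_cfg)
    treatment, control = simulate_peak_replicates(truth, sim_cfg)
    truth_path = outdir / "truth_sites.tsv"
    truth.to_frame().to_csv(truth_path, sep="\t", index=False)
    record("simulate", truth_path)
    for rep in treatment + control:
        p = outdir / f"peaks_{rep.condition}_{rep.replicate_id}.bed"
        write_bed(rep, p)
        record("simulate", p)
    (outdir / "config_resolved.yaml").write_text(
        yaml.safe_dump(resolved, sort_keys=True)
    )
    record("simulate", outdir / "config_resolved.yaml")

    # -- consensus ---------------------------------------------------------
    cons_cfg = ConsensusConfig(
        min_treatment_support=resolved["consensus"]["min_treatment_support"]
    )
    sites = consensus_sites(treatment, control, cons_cfg)
    for rep in control:  # asserted post-condition of the subtraction rule
        idx = IntervalIndex(rep)
        assert not any(idx.overlaps_any(iv) for iv in sites)
    cons_path = outdir / "consensus_sites.bed"
    write_bed(sites, cons_path)
    record("consensus", cons_path)
    summary["n_consensus_sites"] = len(sites)

    # -- matrices & metagenes ---------------------------------------------
    window = resolved["matrix"]["window"]
    bin_size = resolved["matrix"]["bin_size"]
    tracks = simulate_tracks(truth, sim_cfg, assays=("ATAC", "H3K27ac"))
    norm = {k: normalize_per_million(t) for k, t in tracks.items()}
    bimod: dict[str, float] = {}
    for key, track in norm.items():
        m = signal_matrix(track, sites, window=window, bin_size=bin_size, assay=key)
        mpath = outdir / f"matrix_{key.replace(':', '_')}.tsv"
        m.to_tsv(mpath)
        record("matrix", mpath)
        if key.startswith("H3K27ac"):
            bimod[key] = bimodality_index(
                metagene_profile(m), window=window, bin_size=bin_size
            )
    summary["bimodality_index"] = bimod

    # -- classification ----------------------------------------------------
    cls_cfg = resolved["classify"]
    scalars = {}
    calls = {}
    for tp in sim_cfg.timepoints:
        track = norm[f"ATAC:{tp}"]
        scalars[tp] = accessibility_scalars(track, sites)
        thr = accessibility_threshold(
            track,
            seed=resolved["seed"] + 17,
            n_background=cls_cfg["n_background"],
            quantile=cls_cfg["accessibility_quantile"],
            min_fold=cls_cfg["accessibility_min_fold"],
            exclude=sites,
        )
        calls[tp] = scalars[tp] > thr
    site_ids = [iv.name or f"{iv.chrom}:{iv.start}-{iv.end}" for iv in sites]
    profiles = [
        AccessibilityProfile(
            sid,
            tuple(sim_cfg.timepoints),
            tuple(float(scalars[tp][i]) for tp in sim_cfg.timepoints),
        )
        for i, sid in enumerate(site_ids)
    ]
    classifications = classify_types(
        profiles,
        k=cls_cfg["k"],
        seed=resolved["seed"],
        persistence_threshold=cls_cfg["persistence_threshold"],
    )
    cls_path = outdir / "site_classification.tsv"
    pd.DataFrame(
        [
            {
                "site": c.site_id,
                "cluster": c.cluster,
                "type": c.type_label,
                "persistence_ratio": c.persistence_ratio,
            }
            for c in classifications
        ]
    ).to_csv(cls_path, sep="\t", index=False)
    record("classify", cls_path)
    type_counts = pd.Series([c.type_label for c in classifications]).value_counts()
    summary["type_counts"] = type_counts.to_dict()
    first_wd = sim_cfg.timepoints[1]
    table = contingency_from_calls(calls[sim_cfg.timepoints[0]], calls[first_wd])
    stat, p = chi_square_accessibility(table)
    summary["accessibility_chi_square"] = {
        "contingency": table.tolist(),
        "statistic": stat,
        "p_value": p,
    }

    # enhancer categories & retention against the simulated mark evidence
    k4_before, k27_before = truth.mark_peaks(after_withdrawal=False)
    k4_after, k27_after = truth.mark_peaks(after_withdrawal=True)
    sig_before, fracs = enhancer_categories(sites, k4_before, k27_before)
    sig_after, _ = enhancer_categories(sites, k4_after, k27_after)
    type_by_site = {c.site_id: c.type_label for c in classifications}
    retention = enhancer_retention(sig_before, sig_after, type_by_site)
    summary["enhancer_category_fractions"] = {
        k: float(v) for k, v in fracs.items()
    }
    summary["enhancer_retention"] = retention

    # -- annotation --------------------------------------------------------
    ann = resolved["annotate"]
    records, tss_summary = nearest_tss(
        sites, truth.tss, promoter_bp=ann["promoter_bp"], distal_bp=ann["distal_bp"]
    )
    ann_path = outdir / "tss_annotation.tsv"
    pd.DataFrame(
        [
            {"site": r.site_id, "gene": r.gene, "distance": r.distance,
             "category": r.category}
            for r in records
        ]
    ).to_csv(ann_path, sep="\t", index=False)
    record("annotate", ann_path)
    summary["tss"] = tss_summary

    # -- proximity ---------------------------------------------------------
    cof = truth.cofactor_peaks()
    prox_records, median, unmatched = center_distance_stats(
        sites, cof, max_distance=resolved["proximity"]["max_distance"]
    )
    prox_path = outdir / "cofactor_proximity.tsv"
    pd.DataFrame(
        [
            {"site": r.site_id,
             "distance": "" if r.distance is None else r.distance}
            for r in prox_records
        ]
    ).to_csv(prox_path, sep="\t", index=False)
    record("proximity", prox_path)
    summary["cofactor_proximity"] = {
        "median_distance": median,
        "n_unmatched": unmatched,
    }

    # -- expression signature ---------------------------------------------
    expr = simulate_expression(truth, sim_cfg)
    sig = resolved["signature"]
    down, up = expression_signature(
        expr,
        fold_threshold=sig["fold_threshold"],
        sc_expressed_min=sig["sc_expressed_min"],
    )
    expr_path = outdir / "expression.tsv"
    expr.to_csv(expr_path, sep="\t")
    record("signature", expr_path)
    sig_path = outdir / "expression_signature.tsv"
    pd.DataFrame(
        {"gene": down + up, "direction": ["down"] * len(down) + ["up"] * len(up)}
    ).to_csv(sig_path, sep="\t", index=False)
    record("signature", sig_path)
    summary["signature"] = {"n_down": len(down), "n_up": len(up)}

    # -- PCA ---------------------------------------------------------------
    if resolved["pca"]["enabled"]:
        panel, meta, bound = simulate_accessibility_panel(
            truth, sim_cfg,
            n_background_sites=resolved["pca"]["n_background_sites"],
        )
        coords_all, ev_all = pca_samples(panel, n_components=3)
        coords_restricted, ev_restricted = pca_samples(
            panel, restrict_to=bound, n_components=3
        )
        pca_path = outdir / "pca_coordinates.tsv"
        joined = coords_all.join(coords_restricted, rsuffix="_restricted").join(meta)
        joined.to_csv(pca_path, sep="\t")
        record("pca", pca_path)
        summary["pca_explained_variance"] = {
            "all_sites": [float(x) for x in ev_all],
            "restricted": [float(x) for x in ev_restricted],
        }

    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, default=float) + "\n")
    record("summary", summary_path)

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(outdir / "manifest.json")
    return manifest
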