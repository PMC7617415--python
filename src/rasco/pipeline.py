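"""End-to-end pipeline orchestration with a reproducibility manifest.

Stages run in dependency order over plain TSV interchange files:
simulate (optional) -> annotate -> cooccur -> clonality -> spectrum.  Each
stage logs one structured line with row counts, and every output file lands
in the manifest with a sha256 checksum, so a rerun with identical config and
inputs can be verified byte-for-byte on the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotate import (
    ClassificationRules,
    annotate_cohort,
    read_clinical_table,
    read_mutation_table,
    records_to_frame,
)
from .braf_channels import causal_channel_audit
from .clonality import run_pair_table
from .cooccur import (
    BrafClass,
    association_to_row,
    build_table,
    cohort_summary,
    fisher_exact_2x2,
    has_additional_ras,
    is_class,
)
from .simulate import CatalogConfig, CohortConfig, ReadSimConfig, generate_catalog, generate_cohort, generate_read_counts
from .spectra import spectra_from_catalog, spectra_to_frame

log = logging.getLogger("rasco")

_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "out_prefix", "simulate", "annotate", "cooccur", "clonality", "spectrum"},
    "simulate": {"n_tumors", "n_mutations", "n_samples", "mutations_per_sample"},
    "annotate": {"mutations", "clinical", "rules"},
    "cooccur": {"annotated", "contrasts"},
    "clonality": {"reads", "purity", "pairs", "segments", "cn_map", "alpha"},
    "spectrum": {"catalog", "causal_set"},
}


class ConfigError(ValueError):
    pass


def validate_config(cfg: dict) -> None:
    unknown = set(cfg) - _SCHEMA[""]
    if unknown:
        raise ConfigError(f"unknown config key: {sorted(unknown)[0]!r}")
    for section, allowed in _SCHEMA.items():
        if section and section in cfg and cfg[section] is not None:
            bad = set(cfg[section]) - allowed
            if bad:
                raise ConfigError(f"unknown key {sorted(bad)[0]!r} in section {section!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict, stage: str) -> None:
    df.to_csv(path, sep="\t", index=False)
    manifest["outputs"].append(
        {"stage": stage, "path": path.name, "rows": int(len(df)), "sha256": _sha256(path)}
    )
    log.info("stage=%s output=%s rows=%d", stage, path.name, len(df))


def run_pipeline(config_path: str | Path, out_dir: str | Path) -> dict:
    """Run the configured stages; returns (and writes) the run manifest."""
    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text()) or {}
    validate_config(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest: dict = {
        "tool": "rasco",
        "version": __version__,
        "config_sha256": hashlib.sha256(config_path.read_bytes()).hexdigest(),
        "seed": seed,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": [],
        "outputs": [],
        "errors": [],
    }

    paths: dict[str, Path] = {}
    try:
        if cfg.get("simulate") is not None:
            sim = cfg["simulate"] or {}
            manifest["stages"].append("simulate")
            muts, clin = generate_cohort(
                CohortConfig(n_tumors=int(sim.get("n_tumors", 2000))), seed=seed
            )
            reads = generate_read_counts(
                ReadSimConfig(n_mutations=int(sim.get("n_mutations", 100))), seed=seed
            )
            catalog = generate_catalog(
                CatalogConfig(
                    n_samples=int(sim.get("n_samples", 5)),
                    mutations_per_sample=int(sim.get("mutations_per_sample", 2000)),
                ),
                seed=seed,
            )
            paths["mutations"] = out / "mutations.tsv"
            paths["clinical"] = out / "clinical.tsv"
            paths["catalog"] = out / "catalog.tsv"
            _write(muts, paths["mutations"], manifest, "simulate")
            _write(clin, paths["clinical"], manifest, "simulate")
            _write(reads, out / "reads_truth.tsv", manifest, "simulate")
            _write(catalog, paths["catalog"], manifest, "simulate")

        if cfg.get("annotate") is not None:
            ann = cfg["annotate"] or {}
            manifest["stages"].append("annotate")
            mut_path = Path(ann.get("mutations", paths.get("mutations", "")))
            if not mut_path.is_file():
                raise ConfigError(f"annotate stage: mutation table not found: {mut_path}")
            muts = read_mutation_table(mut_path)
            clin_path = ann.get("clinical", paths.get("clinical"))
            clinical = read_clinical_table(clin_path) if clin_path else None
            rules = (
                ClassificationRules.from_yaml(ann["rules"])
                if ann.get("rules")
                else ClassificationRules.from_yaml()
            )
            all_ids = clinical["sample_id"].tolist() if clinical is not None else None
            records = annotate_cohort(muts, clinical, rules, all_sample_ids=all_ids)
            paths["annotated"] = out / "annotated.tsv"
            _write(records_to_frame(records), paths["annotated"], manifest, "annotate")
            _write(cohort_summary(records), out / "summary.tsv", manifest, "annotate")

            if cfg.get("cooccur") is not None:
                manifest["stages"].append("cooccur")
                rows = []
                for name, cls in [("class2_vs_class1", BrafClass.class2),
                                  ("class3_vs_class1", BrafClass.class3)]:
                    pred_cls = is_class(cls)
                    pred_c1 = is_class(BrafClass.class1)

                    def in_pair(rec, a=pred_cls, b=pred_c1):
                        ra, rb = a(rec), b(rec)
                        if ra is None or rb is None or not (ra or rb):
                            return None
                        return ra
                    table = build_table(
                        records, in_pair, has_additional_ras,
                        row_labels=(cls.value, "class1"),
                        col_labels=("additional_ras", "no_additional_ras"),
                    )
                    rows.append(association_to_row(name, fisher_exact_2x2(table)))
                _write(pd.DataFrame(rows), out / "cooccurrence.tsv", manifest, "cooccur")

        if cfg.get("clonality") is not None:
            clo = cfg["clonality"] or {}
            manifest["stages"].append("clonality")
            reads = pd.read_csv(clo["reads"], sep="\t", dtype={"sample_id": str, "mutation_id": str})
            purity = pd.read_csv(clo["purity"], sep="\t", dtype={"sample_id": str})
            pairs = pd.read_csv(clo["pairs"], sep="\t", dtype=str)
            segments = (
                pd.read_csv(clo["segments"], sep="\t", dtype={"sample_id": str})
                if clo.get("segments")
                else None
            )
            cn_map = (
                pd.read_csv(clo["cn_map"], sep="\t", dtype={"sample_id": str, "mutation_id": str})
                if clo.get("cn_map")
                else None
            )
            calls = run_pair_table(
                reads, purity, pairs, segments=segments, cn_map=cn_map,
                alpha=float(clo.get("alpha", 0.05)),
            )
            _write(calls, out / "clonality.tsv", manifest, "clonality")

        if cfg.get("spectrum") is not None:
            spc = cfg["spectrum"] or {}
            manifest["stages"].append("spectrum")
            cat_path = Path(spc.get("catalog", paths.get("catalog", "")))
            if not cat_path.is_file():
                raise ConfigError(f"spectrum stage: catalog not found: {cat_path}")
            catalog = pd.read_csv(cat_path, sep="\t", dtype={"sample_id": str})
            spectra = spectra_from_catalog(catalog)
            _write(spectra_to_frame(spectra), out / "spectra.tsv", manifest, "spectrum")
            _write(causal_channel_audit(), out / "causal_channels.tsv", manifest, "spectrum")
    except ConfigError:
        raise
    except Exception as exc:  # partial failure: keep completed outputs + error report
        manifest["errors"].append(str(exc))

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
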