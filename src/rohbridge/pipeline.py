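"""End-to-end pipeline orchestration: QC -> pedigree -> ROH -> GRM -> bridge.

A :class:`PipelineConfig` (usually loaded from YAML) names the inputs and
parameters; :func:`run_pipeline` executes the stages in order and writes
the report bundle: QC report, per-animal metrics, ROH segments and
summaries, GRM estimators, the fitted bridge models with provenance, and
the estimated-F_PED class tables.  Stage outputs are cached in the output
directory keyed by a hash of their inputs, so unchanged reruns are
byte-stable and cheap.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .bridge import (DegenerateFitError, class_table, estimate_fped,
                     lrm_by_fullgen, refine, select_model)
from .grm import fgrm
from .pedigree import (effective_size, load_pedigree,
                       pct_complete_first_gen, pedigree_metrics_table)
from .plinkio import (GenotypeDataset, maf_filter, qc_filter,
                      read_plink_binary, read_plink_text)
from .roh import RohParams, call_roh, froh_table, roh_summary

log = logging.getLogger("rohbridge")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class DataError(ValueError):
    """Input data missing or malformed."""


@dataclass
class PipelineConfig:
    pedigree: str | None = None
    genotype_prefix: str | None = None
    genotype_format: str = "bed"  # {bed, ped}
    species: str = "sheep"
    out_dir: str = "rohbridge_out"
    snp_missing_max: float = 0.05
    ind_callrate_min: float = 0.95
    drop_nonautosomal: bool = True
    maf_min: float = 0.05
    roh: RohParams = field(default_factory=RohParams)
    min_n: int = 600
    k_max: int = 8
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        roh_raw = raw.pop("roh", {})
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        try:
            cfg = cls(**raw, roh=RohParams(**roh_raw))
        except (TypeError, ValueError) as e:
            raise ConfigError(str(e)) from e
        return cfg


def _hash_inputs(*parts) -> str:
    h = hashlib.sha256()
    for p in parts:
        h.update(repr(p).encode())
        if isinstance(p, (str, Path)) and Path(p).is_file():
            h.update(Path(p).read_bytes())
    return h.hexdigest()[:16]


class _Cache:
    def __init__(self, out_dir: Path):
        self.path = out_dir / "cache_manifest.json"
        self.manifest = (json.loads(self.path.read_text())
                         if self.path.exists() else {})

    def fresh(self, stage: str, key: str, outputs: list[Path]) -> bool:
        return (self.manifest.get(stage) == key
                and all(p.exists() for p in outputs))

    def record(self, stage: str, key: str):
        self.manifest[stage] = key
        self.path.write_text(json.dumps(self.manifest, indent=2))


def load_genotypes(prefix: str, fmt: str, species: str) -> GenotypeDataset:
    prefix = str(prefix)
    try:
        if fmt == "bed":
            return read_plink_binary(prefix + ".bed", prefix + ".bim",
                                     prefix + ".fam", species=species)
        if fmt == "ped":
            return read_plink_text(prefix + ".ped", prefix + ".map",
                                   species=species)
    except FileNotFoundError as e:
        raise DataError(f"genotype file not found: {e.filename}") from e
    raise ConfigError(f"unknown genotype format {fmt!r}")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every configured stage; returns {stage: artifact paths}."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg.log_level)
    log.info("rohbridge %s, seed %d", __version__, cfg.seed)
    cache = _Cache(out)
    artifacts: dict[str, list[str]] = {}

    ped_table = None
    if cfg.pedigree:
        stage = "pedigree"
        key = _hash_inputs(cfg.pedigree)
        target = out / "pedigree_metrics.tsv"
        summary_t = out / "pedigree_summary.tsv"
        if cache.fresh(stage, key, [target, summary_t]):
            log.info("pedigree stage cached")
            ped_table = pd.read_csv(target, sep="\t", dtype={"id": str},
                                    float_precision="round_trip")
        else:
            try:
                ped = load_pedigree(cfg.pedigree)
            except Exception as e:
                raise DataError(f"pedigree stage failed: {e}") from e
            ped_table = pedigree_metrics_table(ped)
            ped_table.to_csv(target, sep="\t", index=False)
            summaries = []
            for breed, ids in ped_table.groupby("breed")["id"]:
                sub = Pedigree_subset(ped, set(ids))
                summaries.append({
                    "breed": breed,
                    "n": len(ids),
                    "pct_complete_first_gen": pct_complete_first_gen(sub),
                    "ne": effective_size(sub),
                })
            pd.DataFrame(summaries).to_csv(summary_t, sep="\t", index=False)
            cache.record(stage, key)
        artifacts[stage] = [str(target), str(summary_t)]

    if not cfg.genotype_prefix:
        log.warning("no genotypes configured: pedigree-only report, "
                    "ROH/GRM/bridge stages skipped")
        return artifacts

    suffixes = (".bed", ".bim", ".fam") if cfg.genotype_format == "bed" else (".ped", ".map")
    geno_files = [cfg.genotype_prefix + s for s in suffixes]
    qc_key = _hash_inputs(*geno_files, cfg.snp_missing_max,
                          cfg.ind_callrate_min, cfg.drop_nonautosomal)
    ds = load_genotypes(cfg.genotype_prefix, cfg.genotype_format, cfg.species)
    ds_qc, report = qc_filter(ds, cfg.snp_missing_max, cfg.ind_callrate_min,
                              cfg.drop_nonautosomal)
    (out / "qc_report.json").write_text(report.to_json())
    (out / "qc_report.txt").write_text(str(report) + "\n")
    artifacts["qc"] = [str(out / "qc_report.json"), str(out / "qc_report.txt")]
    log.info("%s", report)

    stage = "roh"
    roh_key = _hash_inputs(qc_key, cfg.roh)
    seg_t, ind_t, sum_t = (out / "roh_segments.tsv",
                           out / "roh_individual.tsv", out / "roh_summary.tsv")
    if cache.fresh(stage, roh_key, [seg_t, ind_t, sum_t]):
        log.info("roh stage cached")
        per_ind = pd.read_csv(ind_t, sep="\t", dtype={"iid": str},
                              float_precision="round_trip")
    else:
        try:
            segments = call_roh(ds_qc, cfg.roh)
            per_ind = froh_table(ds_qc, segments)
        except Exception as e:
            raise DataError(f"roh stage failed: {e}") from e
        segments.to_csv(seg_t, sep="\t", index=False)
        per_ind.to_csv(ind_t, sep="\t", index=False)
        breeds = (ds_qc.samples["breed"] if "breed" in ds_qc.samples else None)
        roh_summary(per_ind, breeds).to_csv(sum_t, sep="\t", index=False)
        cache.record(stage, roh_key)
    artifacts[stage] = [str(seg_t), str(ind_t), str(sum_t)]

    stage = "grm"
    grm_key = _hash_inputs(qc_key, cfg.maf_min)
    grm_t = out / "grm_inbreeding.tsv"
    if cache.fresh(stage, grm_key, [grm_t]):
        log.info("grm stage cached")
        fgrm_tab = pd.read_csv(grm_t, sep="\t", dtype={"iid": str},
                               float_precision="round_trip")
    else:
        try:
            ds_maf = maf_filter(ds_qc, cfg.maf_min)
            fgrm_tab = fgrm(ds_maf)
        except Exception as e:
            raise DataError(f"grm stage failed: {e}") from e
        fgrm_tab.to_csv(grm_t, sep="\t", index=False)
        cache.record(stage, grm_key)
    artifacts[stage] = [str(grm_t)]

    if ped_table is None:
        log.warning("no pedigree configured: bridge stage skipped")
        return artifacts

    table = build_inbreeding_table(ped_table, per_ind, fgrm_tab,
                                   ds_qc.samples, cfg.species)
    table.to_csv(out / "inbreeding_table.tsv", sep="\t", index=False)
    artifacts["table"] = [str(out / "inbreeding_table.tsv")]
    try:
        bundle = fit_bridge(table, species=sorted(table["species"].unique()),
                            min_n=cfg.min_n, k_max=cfg.k_max)
    except DegenerateFitError as e:
        log.warning("bridge stage skipped: %s", e)
        return artifacts
    (out / "bridge_models.json").write_text(json.dumps(
        {k: v for k, v in bundle["models_json"].items()}, indent=2))
    bundle["table2"].to_csv(out / "table_fullgen_models.tsv", sep="\t", index=False)
    for sp, ct in bundle["class_tables"].items():
        ct.to_csv(out / f"table_classes_{sp}.tsv", sep="\t", index=False)
    artifacts["bridge"] = [str(out / "bridge_models.json"),
                           str(out / "table_fullgen_models.tsv")]
    return artifacts


def Pedigree_subset(ped, ids: set):
    """View of a pedigree restricted to some animals (for per-breed stats)."""
    from .pedigree import Pedigree

    records = {a: r for a, r in ped.records.items() if a in ids}
    # drop links to animals outside the subset
    from .pedigree import AnimalRecord

    fixed = {}
    for a, r in records.items():
        fixed[a] = AnimalRecord(
            id=a, sire=r.sire if r.sire in records else None,
            dam=r.dam if r.dam in records else None, sex=r.sex, breed=r.breed,
        )
    return Pedigree(records=fixed)


def build_inbreeding_table(ped_table, per_ind, fgrm_tab, samples, species) -> pd.DataFrame:
    """Join the three coefficient sources into one per-animal table."""
    df = samples[["iid"]].copy()
    df["species"] = (samples["species"] if "species" in samples
                     else species)
    df["breed"] = samples["breed"] if "breed" in samples else ""
    df = df.merge(ped_table[["id", "f_ped", "fullgen"]].rename(columns={"id": "iid"}),
                  on="iid", how="inner")
    df = df.merge(per_ind[["iid", "f_roh"]], on="iid", how="inner")
    df = df.merge(fgrm_tab[["iid", "f_diag"]].rename(columns={"f_diag": "f_grm"}),
                  on="iid", how="inner")
    return df.rename(columns={"iid": "id"})[
        ["id", "species", "breed", "f_ped", "f_roh", "f_grm", "fullgen"]]


def fit_bridge(table: pd.DataFrame, species, min_n: int = 600,
               k_max: int = 8) -> dict:
    """Stratified fits, per-species selection and refinement, class tables."""
    models = lrm_by_fullgen(table, range(0, k_max + 1))
    t2_rows = []
    for k, m in zip(range(0, k_max + 1), models):
        if m is None:
            t2_rows.append({"min_fullgen": k, "n": 0})
            continue
        t2_rows.append({
            "min_fullgen": k, "n": m.n, "n_goats": m.n_goats,
            "n_sheep": m.n_sheep, "r": m.r, "intercept": m.intercept,
            "slope": m.slope, "r_squared": m.r_squared,
        })
    out = {"table2": pd.DataFrame(t2_rows), "models_json": {},
           "selected": {}, "refined": {}, "class_tables": {}}
    for sp in ([species] if isinstance(species, str) else species):
        sel = select_model(models, sp, min_n=min_n)
        ref = refine(sel, table)
        out["selected"][sp] = sel
        out["refined"][sp] = ref
        out["models_json"][sp] = {"selected": sel.to_dict(),
                                  "refined": ref.to_dict()}
        sub = table.loc[(table["species"] == sp)
                        & (table["fullgen"] >= sel.min_fullgen)]
        est = estimate_fped(sub["f_roh"].to_numpy(), ref)
        out["class_tables"][sp] = class_table(est, sub)
    return out
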