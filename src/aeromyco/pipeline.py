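"""End-to-end orchestration: simulate -> screen -> cluster -> quantify ->
classify -> stats, with a manifest of every artifact produced.

All stages communicate in memory; file artifacts are written when an output
directory is given.  A single global seed drives every stochastic stage
through documented per-stage derivation (stage-name hash), so a run is
reproducible from its manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as amio
from .clustering import PATH_SEP, HierarchicalResult, hierarchical_otu_clustering
from .levels import LEVELS
from .profiles import (
    aggregate_to_level,
    classify_predominance,
    euler_counts,
    filter_prevalence,
)
from .quantify import AbundanceMatrix, build_abundance
from .screening import (
    CATEGORY_FUNGAL,
    PreclusterResult,
    ScreenResult,
    exclude_small_samples,
    precluster,
    screen_reads,
)
from .stats import (
    OrdinationResult,
    PermanovaResult,
    euclidean_distances,
    export_model_tables,
    log_transform,
    permanova,
    sammon,
)
from .synth import GeneratorConfig, SyntheticDataset, simulate_study, _config_dict

logger = logging.getLogger(__name__)


def derive_seed(seed: int, stage: str) -> int:
    """Stage-specific sub-seed: stable hash of ``{seed}:{stage}`` below 2^31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Every tunable of the analysis, at the study's default values."""

    seed: int = 0
    generator: GeneratorConfig | None = None  # set for simulated input
    spike_threshold: float = 0.95
    reliability_cut: float = 0.90
    precluster_threshold: float = 0.995
    min_reads: int = 10_000
    predominance_ratio: float = 10.0
    min_prevalence: int = 5
    hmsc_prevalence: int = 20
    pseudo_count: float = 1e-6
    n_perm: int = 999
    calibration_cap: int | None = 20_000
    fpfn_mode: str = "counts"

    def generator_or_default(self) -> GeneratorConfig:
        if self.generator is None:
            self.generator = GeneratorConfig(seed=derive_seed(self.seed, "simulate"))
        return self.generator


@dataclass
class PipelineResult:
    """All stage outputs of one pipeline run."""

    config: PipelineConfig
    dataset: SyntheticDataset | None
    screen: ScreenResult
    counts: pd.DataFrame  # retained samples
    dropped_samples: list
    reps: PreclusterResult
    clustering: HierarchicalResult
    abundance: AbundanceMatrix
    classifications: pd.DataFrame
    euler: dict
    ordinations: dict  # scope -> OrdinationResult
    permanovas: dict  # scope -> PermanovaResult
    exports: dict
    manifest: dict = field(default_factory=dict)

    @property
    def otus(self) -> pd.DataFrame:
        return self.clustering.assignments.drop_duplicates("otu")


def run_pipeline(config: PipelineConfig, outdir=None) -> PipelineResult:
    """Run the full analysis on a simulated study.

    When ``outdir`` is given every artifact is written there and a manifest
    (config echo, per-stage statistics, file checksums) is saved as
    ``manifest.json``.
    """
    gen_cfg = config.generator_or_default()
    logger.info("simulating study (seed=%d)", gen_cfg.seed)
    dataset = simulate_study(gen_cfg)
    return analyse_dataset(dataset, config, outdir=outdir)


def analyse_dataset(dataset: SyntheticDataset, config: PipelineConfig, outdir=None) -> PipelineResult:
    """Screen, cluster, quantify, classify and analyse one dataset."""
    samples = dataset.samples
    sample_ids_per_read = samples["sample_id"].to_numpy(dtype=object)[dataset.sample_idx]

    logger.info("screening %d reads", dataset.n_reads)
    seqs = dataset.codes if dataset.codes is not None else dataset.seq_list
    screen = screen_reads(
        seqs,
        sample_ids_per_read,
        dataset.spike_seqs,
        dataset.placement_probs(),
        placement_rows=dataset.fungal_rows,
        spike_threshold=config.spike_threshold,
        reliability_cut=config.reliability_cut,
    )
    counts, dropped = exclude_small_samples(screen.counts, min_reads=config.min_reads)
    counts = counts.loc[~counts["flagged"]].reset_index(drop=True)
    retained = set(counts["sample_id"])

    fungal = (screen.categories == CATEGORY_FUNGAL) & np.isin(
        sample_ids_per_read, list(retained)
    )
    fungal_rows = np.flatnonzero(fungal)
    logger.info("pre-clustering %d fungal reads", len(fungal_rows))
    read_ids = _read_ids_for(dataset, fungal_rows)
    placements = _placements_for(dataset, fungal_rows, read_ids)
    if dataset.codes is not None:
        fungal_seqs = dataset.codes[fungal_rows]
    else:
        fungal_seqs = [dataset.seq_list[i] for i in fungal_rows]
    reps = precluster(
        fungal_seqs,
        read_ids,
        sample_ids_per_read[fungal_rows],
        threshold=config.precluster_threshold,
        placements=placements,
    )
    logger.info("%d representatives from %d reads", reps.n, len(fungal_rows))

    clustering = hierarchical_otu_clustering(
        reps.seqs,
        reps.placements,
        weights=reps.weights,
        ids=reps.ids,
        reliability_cut=config.reliability_cut,
        rep_threshold=config.precluster_threshold,
        calibration_cap=config.calibration_cap,
        fpfn_mode=config.fpfn_mode,
    )
    logger.info("%d OTUs", clustering.assignments["otu"].nunique())

    raw = _otu_sample_matrix(reps, clustering)
    raw = raw.reindex(index=sorted(retained & set(raw.index))).fillna(0)
    abundance = build_abundance(raw, counts, samples)

    classifications = _classify_all_levels(abundance, clustering, samples, config)
    euler = _euler_all(abundance, samples, config.min_prevalence)

    matrix = filter_prevalence(abundance.normalized, config.min_prevalence)
    transformed = log_transform(matrix, pseudo=config.pseudo_count)
    meta = abundance.samples
    ordinations = {}
    permanovas = {}
    perm_seed = derive_seed(config.seed, "permanova")
    for scope, term_list in (
        ("all", ["method", "habitat", "site", "plot",
                 "method:habitat", "method:site", "method:plot"]),
        ("air", ["habitat", "site", "plot"]),
        ("soil", ["habitat", "site", "plot"]),
    ):
        if scope == "all":
            rows = list(transformed.index)
        else:
            rows = meta.loc[meta["method"] == scope, "sample_id"].tolist()
            rows = [r for r in transformed.index if r in set(rows)]
        if len(rows) < 3:
            continue
        dist = euclidean_distances(transformed.loc[rows])
        ordinations[scope] = sammon(dist)
        meta_sub = meta.set_index("sample_id").loc[rows]
        terms = [
            t
            for t in term_list
            if all(meta_sub[c].nunique() > 1 for c in t.split(":"))
        ]
        if not terms:
            continue
        permanovas[scope] = permanova(
            dist, meta, terms, n_perm=config.n_perm, seed=perm_seed
        )

    exports = export_model_tables(abundance, screen.counts, min_prevalence=config.hmsc_prevalence)

    result = PipelineResult(
        config=config,
        dataset=dataset,
        screen=screen,
        counts=counts,
        dropped_samples=dropped,
        reps=reps,
        clustering=clustering,
        abundance=abundance,
        classifications=classifications,
        euler=euler,
        ordinations=ordinations,
        permanovas=permanovas,
        exports=exports,
    )
    result.manifest = _build_manifest(result)
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def _read_ids_for(dataset: SyntheticDataset, rows: np.ndarray) -> list:
    counts = np.bincount(dataset.sample_idx, minlength=len(dataset.samples))
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    within = np.arange(dataset.n_reads) - starts[dataset.sample_idx]
    sids = dataset.samples["sample_id"].to_numpy(dtype=object)
    return [
        f"{sids[dataset.sample_idx[r]]}|r{within[r]:07d}" for r in rows
    ]


def _placements_for(dataset: SyntheticDataset, rows: np.ndarray, read_ids) -> pd.DataFrame:
    pos_of = {int(r): k for k, r in enumerate(dataset.fungal_rows)}
    sel = np.asarray([pos_of[int(r)] for r in rows], dtype=np.int64)
    probs = dataset.placement_probs()[sel]
    sp = dataset.species_idx[rows]
    data = {"read_id": np.asarray(read_ids, dtype=object)}
    for li, lv in enumerate(LEVELS):
        level_labels = dataset.taxonomy.labels[lv]
        cats = pd.unique(level_labels)
        codes = pd.Categorical(level_labels, categories=cats).codes
        data[lv] = pd.Categorical.from_codes(np.asarray(codes)[sp], categories=cats)
        data[f"p_{lv}"] = probs[:, li]
    return pd.DataFrame(data)


def _otu_sample_matrix(reps: PreclusterResult, clustering: HierarchicalResult) -> pd.DataFrame:
    otus = clustering.assignments["otu"].to_numpy(dtype=object)
    otu_labels, otu_codes = np.unique(otus, return_inverse=True)
    dense = np.zeros((len(otu_labels), len(reps.sample_index)))
    coo = reps.sample_counts.tocoo()
    np.add.at(dense, (otu_codes[coo.row], coo.col), coo.data)
    return pd.DataFrame(dense.T, index=list(reps.sample_index), columns=list(otu_labels))


def _classify_all_levels(abundance, clustering, samples, config) -> pd.DataFrame:
    frames = []
    for level in LEVELS:
        mat = aggregate_to_level(abundance.normalized, clustering.assignments, level)
        calls = classify_predominance(
            mat, samples, ratio=config.predominance_ratio, min_samples=config.min_prevalence
        )
        calls.insert(0, "level", level)
        frames.append(calls)
    return pd.concat(frames, ignore_index=True)


def _euler_all(abundance, samples, min_prevalence) -> dict:
    meta = samples.set_index("sample_id")
    norm = abundance.normalized
    grouping = meta.loc[norm.index, "method"]
    out = {"air_soil": euler_counts(norm, grouping, min_samples=min_prevalence)}
    for method in ("air", "soil"):
        rows = [i for i in norm.index if meta.at[i, "method"] == method]
        sub = norm.loc[rows]
        habitats = meta.loc[rows, "habitat"]
        if habitats.nunique() == 2:
            out[f"habitat_{method}"] = euler_counts(
                sub, habitats, min_samples=min_prevalence
            )
    return out


def _build_manifest(result: PipelineResult) -> dict:
    cfg = result.config
    gen = _config_dict(cfg.generator) if cfg.generator is not None else None
    thresholds = result.clustering.thresholds
    return {
        "config": {
            "seed": cfg.seed,
            "spike_threshold": cfg.spike_threshold,
            "reliability_cut": cfg.reliability_cut,
            "precluster_threshold": cfg.precluster_threshold,
            "min_reads": cfg.min_reads,
            "predominance_ratio": cfg.predominance_ratio,
            "min_prevalence": cfg.min_prevalence,
            "hmsc_prevalence": cfg.hmsc_prevalence,
            "pseudo_count": cfg.pseudo_count,
            "n_perm": cfg.n_perm,
            "calibration_cap": cfg.calibration_cap,
            "fpfn_mode": cfg.fpfn_mode,
            "generator": gen,
        },
        "seeds": {
            "simulate": gen["seed"] if gen else None,
            "permanova": derive_seed(cfg.seed, "permanova"),
        },
        "stages": {
            "n_reads": int(result.dataset.n_reads) if result.dataset else None,
            "n_samples": int(len(result.screen.counts)),
            "n_samples_retained": int(len(result.counts)),
            "dropped_samples": list(result.dropped_samples),
            "n_fungal_reads": int(result.screen.counts["f"].sum()),
            "n_representatives": int(result.reps.n),
            "n_otus": int(result.clustering.assignments["otu"].nunique()),
            "thresholds": thresholds.to_dict(orient="records"),
        },
        "files": {},
    }


def write_outputs(result: PipelineResult, outdir) -> dict:
    """Write every tabular artifact plus the manifest; returns file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}

    def _put(name, df):
        path = outdir / name
        amio.write_tsv(df, path)
        files[name] = path

    _put("counts.tsv", result.screen.counts)
    _put("counts_retained.tsv", result.counts)
    _put("thresholds.tsv", result.clustering.thresholds)
    _put("assignments.tsv", result.clustering.assignments)
    _put("otus.tsv", result.clustering.otu_table(result.reps.weights))
    _put("abundance_raw.tsv", result.abundance.raw.reset_index(names="sample_id"))
    _put(
        "abundance_calibrated.tsv",
        result.abundance.calibrated.reset_index(names="sample_id"),
    )
    _put(
        "abundance_normalized.tsv",
        result.abundance.normalized.reset_index(names="sample_id"),
    )
    _put("classifications.tsv", result.classifications)
    euler_rows = [
        {"comparison": comp, "subset": str(k), "count": v}
        for comp, d in result.euler.items()
        for k, v in d.items()
    ]
    _put("euler.tsv", pd.DataFrame(euler_rows))
    for scope, ordi in result.ordinations.items():
        coords = ordi.coordinates.reset_index(names="sample_id")
        coords["stress"] = ordi.stress
        _put(f"ordination_{scope}.tsv", coords)
    for scope, perm in result.permanovas.items():
        _put(f"permanova_{scope}.tsv", perm.table)
    for name, df in result.exports.items():
        if isinstance(df.index, pd.Index) and df.index.name is None and name != "richness":
            df = df.reset_index(names="sample_id")
        _put(f"{name}.tsv", df)
    _write_krona(result, outdir, files)

    manifest = result.manifest
    manifest["files"] = {
        name: hashlib.sha256(Path(p).read_bytes()).hexdigest() for name, p in files.items()
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    files["manifest.json"] = outdir / "manifest.json"
    return files


def _write_krona(result: PipelineResult, outdir: Path, files: dict) -> None:
    paths = result.otus.set_index("otu")
    totals = result.abundance.normalized.sum(axis=0)
    rows = []
    for otu, total in totals.items():
        leafed = {
            lv: str(paths.at[otu, lv]).rsplit(PATH_SEP, 1)[-1] for lv in LEVELS
        }
        rows.append({"abundance": float(total), **leafed})
    table = pd.DataFrame(rows)
    path = outdir / "krona.txt"
    amio.write_krona_text(table, path)
    files["krona.txt"] = path


def config_from_yaml(path) -> PipelineConfig:
    """Load a PipelineConfig (and optional nested generator) from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    gen = raw.pop("generator", None)
    cfg = PipelineConfig(**raw)
    if gen is not None:
        from .synth import StudyDesign, TaxonomySpec

        tax = gen.pop("taxonomy", None)
        des = gen.pop("design", None)
        if tax is not None:
            tax["divergences"] = tuple(tax.get("divergences", TaxonomySpec().divergences))
            gen["taxonomy"] = TaxonomySpec(**tax)
        if des is not None:
            des["methods"] = tuple(des.get("methods", ("air", "soil")))
            des["plot_roles"] = tuple(tuple(r) for r in des.get("plot_roles", StudyDesign().plot_roles))
            gen["design"] = StudyDesign(**des)
        if "specialist_proportions" in gen:
            gen["specialist_proportions"] = tuple(gen["specialist_proportions"])
        cfg.generator = GeneratorConfig(**gen)
    return cfg
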