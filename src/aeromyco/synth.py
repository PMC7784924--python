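"""Synthetic air/soil fungal metabarcoding study generator.

Emulates a five-city paired design: per site, two natural-core plots, one
natural-edge plot, one urban-edge plot and two urban-core plots, each
sampled by cyclone air sampler and by soil coring in three replicates
(5 x 6 x 2 x 3 = 180 samples).  Each sample's reads are a multinomial
mixture of spike (synthetic internal standard), fungal and non-fungal
templates with category weights (1 : w* : c), where the true fungal amount
w* carries a configurable urban reduction (default fivefold) and lognormal
sample noise.  Fungal reads come from a simulated reference taxonomy with
per-level sequence divergence; reads acquire i.i.d. per-base substitution
errors and two-point placement probabilities (0.95 when a per-level
Bernoulli reliability draw succeeds, 0.50 otherwise).

The generator exists so that every downstream stage of the pipeline is
testable against known ground truth without touching the real archive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import _identity as idt
from .io import write_fasta, write_tsv
from .levels import LEVELS

RELIABLE_PROB = 0.95
UNRELIABLE_PROB = 0.50

#: per-site plot layout: (plot label, habitat, position)
PLOT_ROLES = (
    ("N1", "natural", "core"),
    ("N2", "natural", "core"),
    ("N3", "natural", "edge"),
    ("U1", "urban", "edge"),
    ("U2", "urban", "core"),
    ("U3", "urban", "core"),
)

HABITAT_CLASSES = ("natural-specialist", "urban-specialist", "generalist")


@dataclass(frozen=True)
class TaxonomySpec:
    """Shape and divergence of the simulated reference taxonomy."""

    phyla: int = 2
    classes_per_phylum: int = 2
    orders_per_class: int = 2
    families_per_order: int = 2
    genera_per_family: int = 3
    species_per_genus: int = 3
    #: expected per-base divergence on the edge entering each level
    divergences: tuple = (0.15, 0.10, 0.08, 0.06, 0.045, 0.03)
    length: int = 250

    @property
    def counts(self) -> tuple:
        return (
            self.phyla,
            self.classes_per_phylum,
            self.orders_per_class,
            self.families_per_order,
            self.genera_per_family,
            self.species_per_genus,
        )

    @property
    def n_species(self) -> int:
        return int(np.prod(self.counts))

    def validate(self) -> None:
        if any(c < 1 for c in self.counts):
            raise ValueError("taxonomy counts must all be positive")
        if len(self.divergences) != len(LEVELS):
            raise ValueError(f"need {len(LEVELS)} divergence values")
        if any(not 0 < d <= 0.5 for d in self.divergences):
            raise ValueError("divergences must lie in (0, 0.5]")
        if self.length < 2:
            raise ValueError("reference length must be >= 2")


@dataclass(frozen=True)
class StudyDesign:
    """Sites x plots x methods x replicates layout of the study."""

    sites: int = 5
    replicates: int = 3
    methods: tuple = ("air", "soil")
    plot_roles: tuple = PLOT_ROLES

    @property
    def n_samples(self) -> int:
        return self.sites * len(self.plot_roles) * len(self.methods) * self.replicates

    def sample_frame(self) -> pd.DataFrame:
        rows = []
        for si in range(1, self.sites + 1):
            site = f"S{si}"
            for plot, habitat, position in self.plot_roles:
                for method in self.methods:
                    for rep in range(1, self.replicates + 1):
                        rows.append(
                            {
                                "sample_id": f"{site}-{plot}-{method}-r{rep}",
                                "site": site,
                                "plot": f"{site}-{plot}",
                                "habitat": habitat,
                                "position": position,
                                "method": method,
                                "replicate": rep,
                            }
                        )
        return pd.DataFrame(rows)


def _default_reliability() -> dict:
    return {
        "phylum": 0.99,
        "class": 0.95,
        "order": 0.92,
        "family": 0.90,
        "genus": 0.85,
        "species": 0.75,
    }


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study; the defaults are the study conditions."""

    seed: int
    taxonomy: TaxonomySpec = field(default_factory=TaxonomySpec)
    design: StudyDesign = field(default_factory=StudyDesign)
    #: natural:urban fungal DNA ratio is 1/urban_multiplier (default fivefold)
    urban_multiplier: float = 0.2
    #: (natural-specialist, urban-specialist, generalist) species proportions
    specialist_proportions: tuple = (0.60, 0.02, 0.38)
    #: abundance ratio of a specialist between home and away habitat
    cross_habitat_ratio: float = 20.0
    mean_depth: float = 20_000.0
    #: relative template amounts: spike : fungal : non-fungal = spike_amount : w* : nonfungal_amount
    spike_amount: float = 1.0
    nonfungal_amount: float = 1.0
    base_fungal_amount: float = 5.0
    lognormal_sigma: float = 0.3
    error_rate: float = 0.002
    indel_rate: float = 0.0
    n_spikes: int = 9
    reliability: dict = field(default_factory=_default_reliability)
    n_failed_samples: int = 0

    def validate(self) -> None:
        self.taxonomy.validate()
        if self.mean_depth <= 0:
            raise ValueError("mean read depth must be positive")
        if self.spike_amount <= 0:
            raise ValueError("spike amount must be positive (quantification undefined otherwise)")
        if self.urban_multiplier <= 0:
            raise ValueError("urban multiplier must be positive")
        for p in (*self.specialist_proportions, self.error_rate, self.indel_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.specialist_proportions) - 1.0) > 1e-9:
            raise ValueError("specialist proportions must sum to 1")
        for lv in LEVELS:
            rho = self.reliability[lv]
            if not 0 <= rho <= 1:
                raise ValueError("reliability probabilities must lie in [0, 1]")


@dataclass
class Taxonomy:
    """Reference sequences and labels of the simulated taxonomy."""

    labels: pd.DataFrame  # one row per species, one column per level
    codes: np.ndarray  # (n_species, length) uint8 reference sequences
    spec: TaxonomySpec

    @property
    def n_species(self) -> int:
        return len(self.labels)

    def sequences(self) -> list[str]:
        return idt.decode(self.codes)


_LEVEL_TAGS = ("P", "C", "O", "F", "G", "S")


def build_taxonomy(spec: TaxonomySpec, seed: int) -> Taxonomy:
    """Grow the reference tree by mutating a random root along each edge.

    Each node's sequence is its parent's with Binomial(L, divergence)
    positions substituted; leaves (species) are the references reads are
    later drawn from.  Deterministic given the seed.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    L = spec.length
    nodes = [((), rng.integers(0, 4, size=L, dtype=np.uint8))]
    for li, (count, div) in enumerate(zip(spec.counts, spec.divergences)):
        nxt = []
        for path, codes in nodes:
            stem = path[-1] if path else ""
            for k in range(1, count + 1):
                child = codes.copy()
                n_mut = rng.binomial(L, div)
                if n_mut:
                    pos = rng.choice(L, size=n_mut, replace=False)
                    child[pos] = (child[pos] + rng.integers(1, 4, size=n_mut)) % 4
                nxt.append((path + (f"{stem}{_LEVEL_TAGS[li]}{k}",), child))
        nodes = nxt
    frame = pd.DataFrame([list(p) for p, _ in nodes], columns=list(LEVELS))
    codes = np.stack([c for _, c in nodes])
    return Taxonomy(labels=frame, codes=codes, spec=spec)


def species_truth(taxonomy: Taxonomy, cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Ecological ground truth per species: habitat class, method affinity, abundance."""
    n = taxonomy.n_species
    classes = rng.choice(
        len(HABITAT_CLASSES), size=n, p=list(cfg.specialist_proportions)
    )
    method_w = rng.dirichlet([2.0, 2.0], size=n)
    mean_abund = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    df = taxonomy.labels.copy()
    df.insert(0, "species_id", taxonomy.labels["species"])
    df["habitat_class"] = np.asarray(HABITAT_CLASSES, dtype=object)[classes]
    df["air_weight"] = method_w[:, 0]
    df["soil_weight"] = method_w[:, 1]
    df["mean_abundance"] = mean_abund
    return df


@dataclass
class SyntheticDataset:
    """An in-memory synthetic study with full ground truth."""

    config: GeneratorConfig
    taxonomy: Taxonomy
    species: pd.DataFrame
    samples: pd.DataFrame
    spike_ids: list
    spike_seqs: list
    codes: np.ndarray | None  # (n_reads, L) uint8; None when indels are on
    seq_list: list | None  # variable-length reads (indel mode)
    sample_idx: np.ndarray  # int32 per read
    category: np.ndarray  # int8 per read: 0 spike, 1 fungal, 2 non-fungal
    species_idx: np.ndarray  # int32 per read (-1 for non-fungal/spike)
    reliable: np.ndarray  # (n_fungal, 6) bool
    fungal_rows: np.ndarray  # row index of each fungal read
    sample_truth: pd.DataFrame  # sample_id, w_star, depth, counts per category

    @property
    def n_reads(self) -> int:
        return len(self.sample_idx)

    def read_ids(self) -> list[str]:
        """Read ids "sample|rNNNNNNN", zero-padded so id order = draw order."""
        counts = np.bincount(self.sample_idx, minlength=len(self.samples))
        ids = np.empty(self.n_reads, dtype=object)
        pos = 0
        for si, sid in enumerate(self.samples["sample_id"]):
            c = counts[si]
            ids[pos : pos + c] = [f"{sid}|r{k:07d}" for k in range(c)]
            pos += c
        return list(ids)

    def sequences(self) -> list[str]:
        if self.seq_list is not None:
            return self.seq_list
        return idt.decode(self.codes)

    def placement_probs(self) -> np.ndarray:
        """(n_fungal, 6) placement probabilities for the fungal reads."""
        return np.where(self.reliable, RELIABLE_PROB, UNRELIABLE_PROB)

    def placements_frame(self, read_ids=None) -> pd.DataFrame:
        """Placement table for the fungal reads (taxa + probabilities)."""
        if read_ids is None:
            read_ids = self.read_ids()
        rid = np.asarray(read_ids, dtype=object)[self.fungal_rows]
        sp = self.species_idx[self.fungal_rows]
        probs = self.placement_probs()
        data = {"read_id": rid}
        for li, lv in enumerate(LEVELS):
            level_labels = self.taxonomy.labels[lv]
            cats = pd.unique(level_labels)
            code_of = pd.Series(
                pd.Categorical(level_labels, categories=cats).codes,
            ).to_numpy()
            data[lv] = pd.Categorical.from_codes(code_of[sp], categories=cats)
            data[f"p_{lv}"] = probs[:, li]
        return pd.DataFrame(data)

    def read_truth_frame(self, read_ids=None) -> pd.DataFrame:
        if read_ids is None:
            read_ids = self.read_ids()
        cat_names = np.asarray(["spike", "fungal", "nonfungal"], dtype=object)
        species = np.full(self.n_reads, "", dtype=object)
        fung = self.species_idx >= 0
        species[fung] = self.taxonomy.labels["species"].to_numpy(dtype=object)[
            self.species_idx[fung]
        ]
        return pd.DataFrame(
            {
                "read_id": read_ids,
                "sample_id": self.samples["sample_id"].to_numpy()[self.sample_idx],
                "category": cat_names[self.category],
                "species": species,
            }
        )

    def write(self, outdir, write_reads: bool = True) -> dict:
        """Materialize the dataset as the pipeline's on-disk input formats."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "truth").mkdir(exist_ok=True)
        paths = {}
        read_ids = self.read_ids()
        if write_reads:
            seqs = self.sequences()
            paths["reads"] = outdir / "reads.fasta"
            write_fasta(zip(read_ids, seqs), paths["reads"])
        paths["spikes"] = outdir / "spikes.fasta"
        write_fasta(zip(self.spike_ids, self.spike_seqs), paths["spikes"])
        paths["samples"] = outdir / "samples.tsv"
        write_tsv(self.samples, paths["samples"])
        paths["placements"] = outdir / "placements.tsv"
        write_tsv(self.placements_frame(read_ids), paths["placements"])
        paths["truth_samples"] = outdir / "truth" / "samples.tsv"
        write_tsv(self.sample_truth, paths["truth_samples"])
        paths["truth_species"] = outdir / "truth" / "species.tsv"
        write_tsv(self.species, paths["truth_species"])
        paths["truth_reads"] = outdir / "truth" / "reads.tsv"
        write_tsv(self.read_truth_frame(read_ids), paths["truth_reads"])
        paths["config"] = outdir / "config.yaml"
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(_config_dict(self.config), fh, sort_keys=True)
        return paths


def _config_dict(cfg: GeneratorConfig) -> dict:
    d = asdict(cfg)
    d["taxonomy"]["divergences"] = list(cfg.taxonomy.divergences)
    d["design"]["methods"] = list(cfg.design.methods)
    d["design"]["plot_roles"] = [list(r) for r in cfg.design.plot_roles]
    d["specialist_proportions"] = list(cfg.specialist_proportions)
    return d


def _mutate_block(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. per-base substitution errors over a block of reads."""
    if rate <= 0 or codes.size == 0:
        return codes
    mask = rng.random(codes.shape) < rate
    n_err = int(mask.sum())
    if n_err:
        codes = codes.copy()
        codes[mask] = (codes[mask] + rng.integers(1, 4, size=n_err, dtype=np.uint8)) % 4
    return codes


def _apply_indels(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = []
    bases = "ACGT"
    for ch in seq:
        r = rng.random()
        if r < rate / 2:
            continue  # deletion
        out.append(ch)
        if r >= rate / 2 and r < rate:
            out.append(bases[rng.integers(0, 4)])  # insertion
    return "".join(out) or seq[:1]


def simulate_study(cfg: GeneratorConfig) -> SyntheticDataset:
    """Draw a full synthetic study: reads, placements, spikes and truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    taxonomy = build_taxonomy(cfg.taxonomy, seed=int(rng.integers(0, 2**31)))
    species = species_truth(taxonomy, cfg, rng)
    L = cfg.taxonomy.length
    spike_codes = rng.integers(0, 4, size=(cfg.n_spikes, L), dtype=np.uint8)
    spike_ids = [f"spike{k}" for k in range(1, cfg.n_spikes + 1)]

    samples = cfg.design.sample_frame()
    n_samples = len(samples)
    failed = set()
    if cfg.n_failed_samples:
        failed = set(
            rng.choice(n_samples, size=cfg.n_failed_samples, replace=False).tolist()
        )

    hab_class = species["habitat_class"].to_numpy()
    base_abund = species["mean_abundance"].to_numpy()
    method_w = {
        "air": species["air_weight"].to_numpy(),
        "soil": species["soil_weight"].to_numpy(),
    }
    # a specialist keeps its abundance at home and is ratio-fold rarer away;
    # generalists are unaffected
    hab_mult = {}
    for habitat in ("natural", "urban"):
        mult = np.ones(taxonomy.n_species)
        away = "urban-specialist" if habitat == "natural" else "natural-specialist"
        mult[hab_class == away] = 1.0 / cfg.cross_habitat_ratio
        hab_mult[habitat] = mult

    rho = np.asarray([cfg.reliability[lv] for lv in LEVELS])
    blocks_codes = []
    blocks_sample = []
    blocks_cat = []
    blocks_species = []
    rel_blocks = []
    truth_rows = []

    for si, row in samples.iterrows():
        urban = row["habitat"] == "urban"
        w_star = (
            cfg.base_fungal_amount
            * (cfg.urban_multiplier if urban else 1.0)
            * float(np.exp(cfg.lognormal_sigma * rng.standard_normal()))
        )
        if si in failed:
            # technical failure: 5-50% of the nominal depth
            lo = max(1, int(0.05 * cfg.mean_depth))
            depth = int(rng.integers(lo, max(lo + 1, int(0.5 * cfg.mean_depth))))
        else:
            depth = int(rng.poisson(cfg.mean_depth))
        comp = np.asarray([cfg.spike_amount, w_star, cfg.nonfungal_amount])
        s_n, f_n, p_n = rng.multinomial(depth, comp / comp.sum())

        sp_idx = rng.integers(0, cfg.n_spikes, size=s_n)
        spike_reads = _mutate_block(spike_codes[sp_idx], cfg.error_rate, rng)

        probs = base_abund * hab_mult[row["habitat"]] * method_w[row["method"]]
        probs = probs / probs.sum()
        sp_counts = rng.multinomial(f_n, probs)
        fungal_species = np.repeat(np.arange(taxonomy.n_species), sp_counts).astype(np.int32)
        fungal_reads = _mutate_block(taxonomy.codes[fungal_species], cfg.error_rate, rng)
        rel = rng.random((f_n, len(LEVELS))) < rho[None, :]

        nonfungal_reads = rng.integers(0, 4, size=(p_n, L), dtype=np.uint8)

        blocks_codes.extend([spike_reads, fungal_reads, nonfungal_reads])
        blocks_sample.append(np.full(depth, si, dtype=np.int32))
        blocks_cat.append(
            np.concatenate(
                [
                    np.zeros(s_n, dtype=np.int8),
                    np.ones(f_n, dtype=np.int8),
                    np.full(p_n, 2, dtype=np.int8),
                ]
            )
        )
        spc = np.full(depth, -1, dtype=np.int32)
        spc[s_n : s_n + f_n] = fungal_species
        blocks_species.append(spc)
        rel_blocks.append(rel)
        truth_rows.append(
            {
                "sample_id": row["sample_id"],
                "w_star": w_star,
                "depth": depth,
                "n_spike": int(s_n),
                "n_fungal": int(f_n),
                "n_nonfungal": int(p_n),
                "failed": si in failed,
            }
        )

    codes = np.concatenate(blocks_codes) if blocks_codes else np.empty((0, L), np.uint8)
    sample_idx = np.concatenate(blocks_sample)
    category = np.concatenate(blocks_cat)
    species_idx = np.concatenate(blocks_species)
    reliable = np.concatenate(rel_blocks) if rel_blocks else np.empty((0, 6), bool)
    fungal_rows = np.flatnonzero(category == 1)

    seq_list = None
    if cfg.indel_rate > 0:
        seq_list = [
            _apply_indels(s, cfg.indel_rate, rng) for s in idt.decode(codes)
        ]
        codes = None

    return SyntheticDataset(
        config=cfg,
        taxonomy=taxonomy,
        species=species,
        samples=samples,
        spike_ids=spike_ids,
        spike_seqs=idt.decode(spike_codes),
        codes=codes,
        seq_list=seq_list,
        sample_idx=sample_idx,
        category=category,
        species_idx=species_idx,
        reliable=reliable,
        fungal_rows=fungal_rows,
        sample_truth=pd.DataFrame(truth_rows),
    )
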