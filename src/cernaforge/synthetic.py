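"""Synthetic whole-transcriptome experiment bundles with planted ground truth.

One bundle emulates the statistical structure of a two-group (CON vs LEU,
five replicates each) whole-transcriptome experiment across four RNA classes:

* negative-binomial counts (Var = mu + alpha*mu^2, gene-wise baseline means
  log-uniform over a stated range, common dispersion) with a planted subset of
  features whose group-2 mean is multiplied by 2^(+/-planted_log2fc);
* transcript sequences (mRNA 3'UTRs, lncRNA, circRNA, 23-25 nt mature miRNAs)
  with planted miRNA sites that are perfectly complementary over the miRNA's
  full length, guaranteeing strict seed pairing and passing alignment-score
  and free-energy thresholds;
* positive co-expression among ceRNA partners induced by one shared
  log-normal latent factor per triad, multiplicative on the NB mean;
* a protein-interaction graph with planted near-cliques in a sparse
  Erdos-Renyi background;
* gene-set (GMT) collections with one set enriched in planted differential
  features at a configurable odds.

Everything derives from a single integer seed; a fixed seed yields a
byte-identical bundle. The TruthLedger records every planted object so
downstream stages can be scored for recall and precision.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from . import targets as tp

RNA_CLASSES = ("mRNA", "lncRNA", "circRNA", "miRNA")

_DEFAULT_N_FEATURES = {"mRNA": 300, "lncRNA": 100, "circRNA": 100, "miRNA": 40}
_UTR_LENGTHS = {"mRNA": (300, 800), "lncRNA": (400, 1200), "circRNA": (200, 600)}
_MIRNA_LENGTHS = (23, 25)  # planted miRNAs: full-length complements must pass S >= 150


@dataclass
class SimConfig:
    """Parameters of one synthetic experiment bundle."""

    n_per_group: int = 5
    n_features: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_N_FEATURES))
    de_fraction: float = 0.05
    planted_log2fc: float = 3.0
    nb_dispersion: float = 0.05
    n_triads: int = 8
    seed: int = 42
    clique_sizes: list[int] = field(default_factory=lambda: [9, 9, 9, 9])
    clique_edge_dropout: float = 1.0 / 36.0  # one edge off a 9-clique -> 35 edges
    background_nodes: int = 26
    background_density: float = 0.02
    size_factor_log2_spread: float = 0.5
    latent_sigma: float = 0.5
    mean_range: tuple[float, float] = (20.0, 2000.0)
    n_gene_sets: int = 20
    gene_set_size_range: tuple[int, int] = (30, 80)
    enrichment_odds: float = 8.0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not (0.0 <= self.de_fraction < 1.0):
            raise ValueError("de_fraction must be in [0, 1)")
        if self.de_fraction > 0 and self.planted_log2fc < 2.0:
            raise ValueError("planted_log2fc must be >= 2 so planted features pass the DE cut")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        for cls, n in self.n_features.items():
            if n <= 0:
                raise ValueError(f"non-positive feature count for {cls}")
        if any(s < 3 for s in self.clique_sizes):
            raise ValueError("clique sizes must be >= 3")
        if self.n_triads < 0:
            raise ValueError("n_triads must be >= 0")
        max_sets = self.gene_set_size_range[1]
        if max_sets > self.n_features.get("mRNA", 0):
            raise ValueError("gene-set size exceeds the mRNA universe")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("mean_range", "gene_set_size_range"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class TruthLedger:
    """Planted ground truth of one bundle."""

    de_features: dict[str, dict[str, str]]  # class -> {feature_id: 'up'/'down'}
    true_targets: list[tuple[str, str, str]]  # (mirna_id, transcript_id, class)
    true_triads: list[dict]  # sponge_id, sponge_class, mirna_id, mrna_id
    true_modules: list[list[str]]
    enriched_set: str | None = None

    def to_json(self, path: str | Path) -> None:
        cio.write_json(
            {
                "de_features": self.de_features,
                "true_targets": [list(t) for t in self.true_targets],
                "true_triads": self.true_triads,
                "true_modules": self.true_modules,
                "enriched_set": self.enriched_set,
            },
            path,
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthLedger":
        d = cio.read_json(path)
        return cls(
            de_features=d["de_features"],
            true_targets=[tuple(t) for t in d["true_targets"]],
            true_triads=d["true_triads"],
            true_modules=d["true_modules"],
            enriched_set=d.get("enriched_set"),
        )


@dataclass
class SimBundle:
    config: SimConfig
    counts: dict[str, pd.DataFrame]
    samples: pd.Series  # sample_id -> group
    sequences: dict[str, dict[str, str]]  # class -> {id: DNA sequence}
    interactions: list[tuple[str, str]]
    gene_sets: dict[str, list[str]]
    truth: TruthLedger


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _feature_ids(rna_class: str, n: int) -> list[str]:
    prefix = {"mRNA": "gene", "lncRNA": "lnc", "circRNA": "circ", "miRNA": "mir"}[rna_class]
    width = max(4, len(str(n)))
    return [f"{prefix}_{i + 1:0{width}d}" for i in range(n)]


def _sample_ids(n_per_group: int) -> tuple[list[str], pd.Series]:
    ids = [f"CON_{i + 1}" for i in range(n_per_group)] + [
        f"LEU_{i + 1}" for i in range(n_per_group)
    ]
    groups = pd.Series(
        ["CON"] * n_per_group + ["LEU"] * n_per_group, index=ids, name="group"
    )
    return ids, groups


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws with Var = mu + dispersion*mu^2 (gamma-Poisson mixture form)."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def generate_counts(
    config: SimConfig,
    rna_class: str,
    rng: np.random.Generator | None = None,
    forced_de: dict[str, str] | None = None,
    latent_log: dict[str, np.ndarray] | None = None,
) -> tuple[pd.DataFrame, pd.Series, dict[str, str]]:
    """Counts for one RNA class plus the planted-DE ledger fragment.

    ``forced_de`` pins specific features (triad members) to a direction in
    addition to the random de_fraction subset; ``latent_log`` supplies a
    per-feature log-scale latent offset per sample (ceRNA co-expression).
    Returns (counts, sample groups, {feature: direction}).
    """
    if rna_class not in RNA_CLASSES:
        raise ValueError(f"unknown RNA class {rna_class!r}")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    n = config.n_features[rna_class]
    ids = _feature_ids(rna_class, n)
    sample_ids, groups = _sample_ids(config.n_per_group)

    lo, hi = config.mean_range
    base_mean = 10.0 ** rng.uniform(math.log10(lo), math.log10(hi), size=n)
    spread = config.size_factor_log2_spread
    size_factors = 2.0 ** rng.uniform(-spread / 2.0, spread / 2.0, size=len(sample_ids))

    n_de = int(round(config.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    directions = {ids[i]: ("up" if rng.random() < 0.5 else "down") for i in sorted(de_idx)}
    for feat, direction in (forced_de or {}).items():
        directions[feat] = direction

    log2fc = np.zeros(n)
    for i, feat in enumerate(ids):
        if feat in directions:
            log2fc[i] = config.planted_log2fc if directions[feat] == "up" else -config.planted_log2fc

    is_leu = (groups == "LEU").to_numpy()
    mean = base_mean[:, None] * size_factors[None, :]
    mean = mean * np.where(is_leu[None, :], 2.0 ** log2fc[:, None], 1.0)
    if latent_log:
        for feat, offsets in latent_log.items():
            if feat in ids:
                mean[ids.index(feat)] *= np.exp(offsets)
    counts = _nb_draw(rng, mean, config.nb_dispersion)
    df = pd.DataFrame(counts, index=pd.Index(ids, name="feature_id"), columns=sample_ids)
    return df, groups, directions


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _dna_site_for(mirna_dna: str) -> str:
    """The perfectly complementary (antiparallel) DNA target site."""
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    return "".join(comp[b] for b in reversed(mirna_dna))


def _draw_mirna(rng: np.random.Generator) -> str:
    """A mature-miRNA DNA sequence whose perfect-complement duplex passes both
    the S >= 150 and dG <= -30 thresholds (rejection sampling)."""
    while True:
        length = int(rng.integers(_MIRNA_LENGTHS[0], _MIRNA_LENGTHS[1] + 1))
        seq = _random_dna(rng, length)
        site = _dna_site_for(seq)
        if tp.align_score(seq, site) >= tp.S_MIN_DEFAULT and tp.duplex_energy(seq, site) <= tp.G_MAX_DEFAULT:
            return seq


def _insert_site(
    rng: np.random.Generator, transcript: str, site: str, occupied: list[tuple[int, int]]
) -> tuple[str, int]:
    """Overwrite the transcript with the site at a random free position."""
    if len(site) > len(transcript):
        raise ValueError("requested site longer than host transcript")
    for _ in range(200):
        start = int(rng.integers(0, len(transcript) - len(site) + 1))
        span = (start, start + len(site) - 1)
        if all(span[1] < s or span[0] > e for s, e in occupied):
            occupied.append(span)
            return transcript[: span[0]] + site + transcript[span[1] + 1 :], start
    raise ValueError("could not place site without overlapping an existing one")


def generate_sequences(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    triads: list[dict] | None = None,
) -> tuple[dict[str, dict[str, str]], list[tuple[str, str, str]]]:
    """Transcript FASTA records plus the planted (miRNA, transcript) pairs.

    Background transcripts are i.i.d. uniform DNA; each planted pair receives
    one inserted site perfectly complementary to the miRNA's full length.
    circRNA records are linearizations whose backsplice junction sits between
    the last and first nucleotide.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    seqs: dict[str, dict[str, str]] = {}
    for cls in ("mRNA", "lncRNA", "circRNA"):
        lo, hi = _UTR_LENGTHS[cls]
        seqs[cls] = {
            fid: _random_dna(rng, int(rng.integers(lo, hi + 1)))
            for fid in _feature_ids(cls, config.n_features[cls])
        }
    seqs["miRNA"] = {fid: _draw_mirna(rng) for fid in _feature_ids("miRNA", config.n_features["miRNA"])}

    true_targets: list[tuple[str, str, str]] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    for triad in triads or []:
        mirna_dna = seqs["miRNA"][triad["mirna_id"]]
        site = _dna_site_for(mirna_dna)
        for t_id, t_cls in (
            (triad["mrna_id"], "mRNA"),
            (triad["sponge_id"], triad["sponge_class"]),
        ):
            pair = (triad["mirna_id"], t_id, t_cls)
            if pair in true_targets:
                continue
            seqs[t_cls][t_id], _ = _insert_site(
                rng, seqs[t_cls][t_id], site, occupied.setdefault(t_id, [])
            )
            true_targets.append(pair)
    return seqs, true_targets


def plant_junction_site(circ_seq: str, mirna_dna: str, rng: np.random.Generator) -> str:
    """Rewrite a circRNA so a perfect site for the miRNA spans the backsplice
    junction (detected only by junction-aware scanning)."""
    site = _dna_site_for(mirna_dna)
    if len(site) > len(circ_seq):
        raise ValueError("requested site longer than host transcript")
    with_site = site + circ_seq[len(site) :]
    shift = len(site) // 2  # split the site across the linearization boundary
    return with_site[shift:] + with_site[:shift]


# ---------------------------------------------------------------------------
# interaction graph
# ---------------------------------------------------------------------------

def generate_interaction_graph(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[tuple[str, str]], list[list[str]]]:
    """Planted near-cliques in an Erdos-Renyi background over mRNA ids.

    Each planted module is a clique with a ``clique_edge_dropout`` fraction of
    its edges removed (rounded); planted node sets are disjoint. Background
    edges are sampled at ``background_density`` over pairs with at least one
    non-planted endpoint, so planted modules stay separable.
    Returns (edge list, planted node sets).
    """
    if not config.clique_sizes:
        raise ValueError("clique_sizes must be nonempty")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    mrna_ids = _feature_ids("mRNA", config.n_features["mRNA"])
    needed = sum(config.clique_sizes) + config.background_nodes
    if needed > len(mrna_ids):
        raise ValueError("not enough mRNA features for the requested graph")
    chosen = list(rng.choice(mrna_ids, size=needed, replace=False))
    modules: list[list[str]] = []
    edges: set[tuple[str, str]] = set()
    cursor = 0
    for size in config.clique_sizes:
        members = sorted(chosen[cursor : cursor + size])
        cursor += size
        clique_edges = [tuple(sorted(e)) for e in itertools.combinations(members, 2)]
        n_drop = int(round(config.clique_edge_dropout * len(clique_edges)))
        drop_idx = set(rng.choice(len(clique_edges), size=n_drop, replace=False)) if n_drop else set()
        edges.update(e for i, e in enumerate(clique_edges) if i not in drop_idx)
        modules.append(members)
    planted_nodes = set().union(*(set(m) for m in modules))
    all_nodes = sorted(chosen)
    for a, b in itertools.combinations(all_nodes, 2):
        if a in planted_nodes and b in planted_nodes:
            continue
        if rng.random() < config.background_density:
            edges.add(tuple(sorted((a, b))))
    return sorted(edges), modules


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def generate_gene_sets(
    config: SimConfig,
    de_mrna: dict[str, str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, list[str]], str]:
    """Random GMT sets over the mRNA universe plus one set enriched in
    planted differential mRNAs at ``enrichment_odds`` sampling odds.

    Returns (gene sets, name of the enriched set).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    universe = _feature_ids("mRNA", config.n_features["mRNA"])
    lo, hi = config.gene_set_size_range
    if hi > len(universe):
        raise ValueError("gene-set size exceeds the universe")
    sets: dict[str, list[str]] = {}
    for i in range(config.n_gene_sets):
        size = int(rng.integers(lo, hi + 1))
        members = sorted(rng.choice(universe, size=size, replace=False))
        sets[f"SET_{i + 1:03d}"] = members
    de_ids = set(de_mrna or {})
    weights = np.array(
        [config.enrichment_odds if g in de_ids else 1.0 for g in universe], dtype=float
    )
    weights /= weights.sum()
    size = int(rng.integers(lo, hi + 1))
    enriched_name = "SET_ENRICHED"
    sets[enriched_name] = sorted(rng.choice(universe, size=size, replace=False, p=weights))
    return sets, enriched_name


# ---------------------------------------------------------------------------
# full bundle
# ---------------------------------------------------------------------------

def generate_bundle(config: SimConfig) -> SimBundle:
    """The complete deterministic bundle: counts for all four classes,
    sequences, interaction graph, gene sets, and the truth ledger."""
    ss = np.random.SeedSequence(config.seed)
    rngs = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("plan", "mRNA", "lncRNA", "circRNA", "miRNA", "sequences", "graph", "genesets"),
            ss.spawn(8),
        )
    }

    triads = _plan_triads(config, rngs["plan"])
    latent = _plan_latent(config, triads, rngs["plan"])

    forced: dict[str, dict[str, str]] = {cls: {} for cls in RNA_CLASSES}
    for t in triads:
        forced["mRNA"][t["mrna_id"]] = t["dir_pair"]
        forced[t["sponge_class"]][t["sponge_id"]] = t["dir_pair"]
        forced["miRNA"][t["mirna_id"]] = t["dir_mirna"]

    counts: dict[str, pd.DataFrame] = {}
    de_features: dict[str, dict[str, str]] = {}
    samples = None
    for cls in RNA_CLASSES:
        df, groups, directions = generate_counts(
            config, cls, rng=rngs[cls], forced_de=forced[cls], latent_log=latent.get(cls)
        )
        counts[cls] = df
        de_features[cls] = directions
        samples = groups

    sequences, true_targets = generate_sequences(config, rng=rngs["sequences"], triads=triads)
    interactions, modules = generate_interaction_graph(config, rng=rngs["graph"])
    gene_sets, enriched = generate_gene_sets(config, de_features["mRNA"], rng=rngs["genesets"])

    truth = TruthLedger(
        de_features=de_features,
        true_targets=true_targets,
        true_triads=[
            {k: t[k] for k in ("sponge_id", "sponge_class", "mirna_id", "mrna_id")}
            for t in triads
        ],
        true_modules=modules,
        enriched_set=enriched,
    )
    return SimBundle(
        config=config,
        counts=counts,
        samples=samples,
        sequences=sequences,
        interactions=interactions,
        gene_sets=gene_sets,
        truth=truth,
    )


def _plan_triads(config: SimConfig, rng: np.random.Generator) -> list[dict]:
    """Choose the planted ceRNA triads.

    Triads come in lncRNA/circRNA pairs sharing the same miRNA and mRNA, so
    the integrated network (miRNA must sponge both classes) is non-empty by
    construction. Sponge and mRNA share a DE direction (positive
    co-expression); the miRNA direction is drawn independently.
    """
    n = config.n_triads
    if n == 0:
        return []
    n_pairs = (n + 1) // 2
    for cls, need in (("mRNA", n_pairs), ("miRNA", n_pairs), ("lncRNA", n_pairs), ("circRNA", n // 2)):
        if need > config.n_features[cls]:
            raise ValueError(f"n_triads needs more {cls} features than configured")
    mrna = rng.choice(_feature_ids("mRNA", config.n_features["mRNA"]), size=n_pairs, replace=False)
    mir = rng.choice(_feature_ids("miRNA", config.n_features["miRNA"]), size=n_pairs, replace=False)
    lnc = rng.choice(_feature_ids("lncRNA", config.n_features["lncRNA"]), size=n_pairs, replace=False)
    circ = rng.choice(
        _feature_ids("circRNA", config.n_features["circRNA"]), size=n // 2, replace=False
    )
    triads: list[dict] = []
    for i in range(n_pairs):
        dir_pair = "up" if rng.random() < 0.5 else "down"
        dir_mirna = "up" if rng.random() < 0.5 else "down"
        triads.append(
            {
                "sponge_id": str(lnc[i]),
                "sponge_class": "lncRNA",
                "mirna_id": str(mir[i]),
                "mrna_id": str(mrna[i]),
                "dir_pair": dir_pair,
                "dir_mirna": dir_mirna,
            }
        )
        if len(triads) < n and i < len(circ):
            triads.append(
                {
                    "sponge_id": str(circ[i]),
                    "sponge_class": "circRNA",
                    "mirna_id": str(mir[i]),
                    "mrna_id": str(mrna[i]),
                    "dir_pair": dir_pair,
                    "dir_mirna": dir_mirna,
                }
            )
    return triads[:n]


def _plan_latent(
    config: SimConfig, triads: list[dict], rng: np.random.Generator
) -> dict[str, dict[str, np.ndarray]]:
    """One shared log-normal factor per miRNA family of triads, applied
    multiplicatively to the sponge and mRNA means.

    The log offsets are centered within each group so the factor induces
    co-expression without perturbing the planted between-group fold change.
    """
    latent: dict[str, dict[str, np.ndarray]] = {}
    n = config.n_per_group
    sigma = config.latent_sigma
    factors_by_mirna: dict[str, np.ndarray] = {}
    for t in triads:
        if t["mirna_id"] not in factors_by_mirna:
            draw = rng.normal(0.0, sigma, size=2 * n)
            draw[:n] -= draw[:n].mean()
            draw[n:] -= draw[n:].mean()
            factors_by_mirna[t["mirna_id"]] = draw
        offsets = factors_by_mirna[t["mirna_id"]]
        latent.setdefault("mRNA", {})[t["mrna_id"]] = offsets
        latent.setdefault(t["sponge_class"], {})[t["sponge_id"]] = offsets
    return latent


def write_bundle(bundle: SimBundle, outdir: str | Path) -> None:
    """Serialize a bundle to its on-disk layout (tab-separated tables, FASTA,
    GMT, truth.json, config.json)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for cls in RNA_CLASSES:
        cio.write_counts(bundle.counts[cls], outdir / f"counts_{cls}.tsv")
        cio.write_fasta(bundle.sequences[cls], outdir / f"sequences_{cls}.fasta")
    cio.write_samples(bundle.samples, outdir / "samples.tsv")
    cio.write_edge_list(bundle.interactions, outdir / "interactions.tsv")
    cio.write_gmt(bundle.gene_sets, outdir / "genesets.gmt")
    bundle.truth.to_json(outdir / "truth.json")
    cfg = dataclasses.asdict(bundle.config)
    with open(outdir / "config.json", "w", encoding="utf-8") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True, default=list)
        fh.write("\n")
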