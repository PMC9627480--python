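"""Synthetic inputs with the statistical structure the analysis assumes.

The curated inputs behind an oviductal miRNome study — literature-derived
miRNA lists, database snapshots of target predictions and interaction
confidences — are not redistributable, so every pipeline stage here is
exercised on generated tables whose ground truth is known:

* a miRNA → target table whose score filter (>90) retains a planted gene
  set, sized by default so that roughly 2,700 pairs over roughly 2,600
  distinct genes survive the filter — the scale of the real network;
* an interaction table derived from a planted graph, with true edges given
  confidences in [0.700, 0.999] and decoy non-edges in [0.150, 0.699], so
  the 0.700 cutoff recovers the planted graph losslessly;
* a preferential-attachment graph as the heavy-tailed connectivity model
  (hand-grown with a documented seed convention: an initial clique of m+1
  nodes, then each new node attaches m degree-proportional edges, giving
  exactly m*(n-m-1) + C(m+1, 2) edges);
* annotation tables with planted enriched terms over-sampling a hub list;
* phenotype records sampled from the keyword families of the two study
  categories plus neutral terms.

Every generator is a pure function of its arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import networkx as nx
import numpy as np

from .data_io import AnnotationSet, InteractionRecord, PhenotypeRecord, TargetRecord
from .network_build import GeneNetwork

TARGET_SCORE_CUTOFF = 90.0  # the strict > cutoff the study design fixes


@dataclass
class SyntheticConfig:
    """Study-condition defaults for the synthetic input suite.

    The defaults emulate the real data's scale: with scores Uniform(50, 100)
    a fraction 0.2 of pairs passes the >90 filter, so 60 miRNAs with
    180–270 targets each (~13,500 pairs) over a 20,000-gene pool leave
    ~2,700 retained pairs over ~2,500–2,600 distinct genes; of those, about
    65% are wired into one preferential-attachment component while the rest
    stay isolated.
    """

    seed: int = 0
    n_mirnas: int = 60
    n_genes: int = 20_000
    targets_per_mirna: tuple[int, int] = (180, 270)
    score_range: tuple[float, float] = (50.0, 100.0)
    integer_scores: bool = False
    graph_model: str = "preferential_attachment"
    model_params: dict = dc_field(default_factory=lambda: {"m": 2})
    connected_fraction: float = 0.655
    decoy_rate: float = 1.0
    planted_terms: list[tuple[str, int, bool]] = dc_field(
        default_factory=lambda: [("T:planted1", 40, True), ("T:planted2", 60, True)]
    )
    n_background_terms: int = 40
    background_term_size: tuple[int, int] = (5, 60)
    planted_odds_ratio: float = 20.0

    def __post_init__(self) -> None:
        if self.n_genes < self.targets_per_mirna[1]:
            raise ValueError("n_genes must be >= max targets_per_mirna")


def _gene_name(i: int) -> str:
    return f"G{i:05d}"


# ---------------------------------------------------------------------------
# Graph models
# ---------------------------------------------------------------------------


def generate_preferential_attachment(n: int, m: int, seed: int) -> GeneNetwork:
    """Grow a preferential-attachment (scale-free) graph on n gene nodes.

    Convention: start from a complete graph on m+1 nodes; each subsequent
    node attaches m edges to distinct existing nodes chosen with probability
    proportional to current degree. The result is connected with exactly
    m*(n-m-1) + (m+1)m/2 edges, deterministic per seed.
    """
    if not 1 <= m < n:
        raise ValueError("need 1 <= m < n")
    rng = np.random.default_rng(seed)
    g = nx.complete_graph(m + 1)
    # degree-proportional sampling via a repeated-endpoint list
    endpoints: list[int] = [v for e in g.edges for v in e]
    for new in range(m + 1, n):
        targets: set[int] = set()
        while len(targets) < m:
            targets.add(endpoints[rng.integers(len(endpoints))])
        for t in targets:
            g.add_edge(new, t)
            endpoints.extend((new, t))
    relabel = {v: _gene_name(v) for v in g.nodes}
    return GeneNetwork(graph=nx.relabel_nodes(g, relabel), label="synthetic_pa")


def generate_erdos_renyi(n: int, p: float, seed: int) -> GeneNetwork:
    """G(n, p) null model (each pair independently with probability p)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    g = nx.fast_gnp_random_graph(n, p, seed=int(seed))
    relabel = {v: _gene_name(v) for v in g.nodes}
    return GeneNetwork(graph=nx.relabel_nodes(g, relabel), label="synthetic_er")


# ---------------------------------------------------------------------------
# Tabular generators
# ---------------------------------------------------------------------------


def generate_target_table(
    config: SyntheticConfig,
) -> tuple[list[TargetRecord], set[str]]:
    """Draw the miRNA→target table; return records plus the >90 truth gene set.

    Each miRNA receives Uniform{min..max} targets sampled without
    replacement from the gene pool; scores are Uniform(low, high) reals
    (or integers with ``integer_scores``, exercising the strict-boundary
    case at exactly 90).
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.targets_per_mirna
    s_lo, s_hi = config.score_range
    records: list[TargetRecord] = []
    truth: set[str] = set()
    for i in range(config.n_mirnas):
        mirna = f"mmu-miR-s{i + 1:03d}"
        k = int(rng.integers(lo, hi + 1))
        genes = rng.choice(config.n_genes, size=k, replace=False)
        if config.integer_scores:
            scores = rng.integers(int(s_lo), int(s_hi) + 1, size=k).astype(float)
        else:
            scores = rng.uniform(s_lo, s_hi, size=k)
        for gi, score in zip(genes, scores):
            gene = _gene_name(int(gi))
            records.append(TargetRecord(mirna, gene, float(score)))
            if score > TARGET_SCORE_CUTOFF:
                truth.add(gene)
    return records, truth


def generate_interaction_table(
    network: GeneNetwork,
    seed: int,
    decoy_rate: float = 1.0,
    decoy_pool: set[str] | None = None,
) -> tuple[list[InteractionRecord], set[frozenset[str]]]:
    """Emit confidence-scored interactions for a planted graph.

    True edges get confidence ~ Uniform(0.700, 0.999); ``decoy_rate`` times
    as many non-edges (drawn from ``decoy_pool``, default the graph's
    nodes) get Uniform(0.150, 0.699). Filtering at >= 0.700 therefore
    recovers exactly the planted edge set (the returned ground truth).
    """
    rng = np.random.default_rng(seed)
    edges = sorted(tuple(sorted(e)) for e in network.graph.edges)
    records = [
        InteractionRecord(a, b, float(rng.uniform(0.700, 0.999))) for a, b in edges
    ]
    truth = {frozenset(e) for e in edges}
    pool = sorted(decoy_pool) if decoy_pool is not None else sorted(network.graph.nodes)
    n_decoys = int(round(decoy_rate * len(edges)))
    seen: set[tuple[str, str]] = set(edges)
    made = 0
    while made < n_decoys and len(pool) >= 2:
        i, j = rng.integers(len(pool)), rng.integers(len(pool))
        if i == j:
            continue
        pair = tuple(sorted((pool[i], pool[j])))
        if pair in seen:
            continue
        seen.add(pair)
        records.append(
            InteractionRecord(pair[0], pair[1], float(rng.uniform(0.150, 0.699)))
        )
        made += 1
    return records, truth


def generate_annotations(
    genes: set[str],
    planted_terms: list[tuple[str, int, bool]],
    hub_genes: set[str],
    seed: int,
    n_background_terms: int = 40,
    background_term_size: tuple[int, int] = (5, 60),
    odds_ratio: float = 20.0,
) -> tuple[AnnotationSet, list[str]]:
    """Build a term→gene annotation set with optionally planted enrichment.

    Background terms sample genes uniformly; a planted term with the
    enriched flag samples hub genes with ``odds_ratio``-fold weight, so the
    over-representation stage has a known positive. Returns the annotation
    set and the list of planted-enriched term ids.
    """
    if not genes:
        raise ValueError("empty gene list")
    rng = np.random.default_rng(seed)
    gene_list = sorted(genes)
    hub_mask = np.array([g in hub_genes for g in gene_list], dtype=float)
    terms: dict[str, frozenset[str]] = {}
    truth: list[str] = []

    lo, hi = background_term_size
    for i in range(n_background_terms):
        size = int(rng.integers(lo, min(hi, len(gene_list)) + 1))
        chosen = rng.choice(len(gene_list), size=size, replace=False)
        terms[f"T:bg{i + 1:03d}"] = frozenset(gene_list[j] for j in chosen)

    for term_id, size, enriched in planted_terms:
        size = min(size, len(gene_list))
        if enriched and hub_mask.any():
            weights = 1.0 + (odds_ratio - 1.0) * hub_mask
            p = weights / weights.sum()
            chosen = rng.choice(len(gene_list), size=size, replace=False, p=p)
            truth.append(term_id)
        else:
            chosen = rng.choice(len(gene_list), size=size, replace=False)
        terms[term_id] = frozenset(gene_list[j] for j in chosen)
    return AnnotationSet(terms), truth


_PHENO_TEMPLATES = {
    "reproductive_system": [
        "small testis", "abnormal testis morphology", "male infertility",
        "female infertility", "abnormal uterus morphology",
        "abnormal ovary morphology", "small epididymis",
        "abnormal seminal vesicle morphology",
    ],
    "embryo": [
        "abnormal embryo size", "embryonic growth retardation",
        "abnormal placenta size", "abnormal neural tube morphology",
        "abnormal visceral yolk sac morphology",
        "abnormal umbilical cord morphology",
    ],
    "other": [
        "increased body weight", "decreased locomotor activity",
        "abnormal coat appearance", "decreased grip strength",
        "abnormal gait",
    ],
}


def generate_phenotypes(
    genes: list[str] | set[str],
    seed: int,
    category_probs: tuple[float, float, float] = (0.2, 0.25, 0.55),
) -> tuple[list[PhenotypeRecord], list[str]]:
    """Sample one KO-phenotype record per gene, category unlabelled.

    Term strings come from the keyword families of the two study
    categories plus neutral templates (probabilities: reproductive_system,
    embryo, other). Records are emitted with category ``other`` so the
    keyword classifier is exercised; the true categories are returned
    alongside.
    """
    rng = np.random.default_rng(seed)
    cats = ("reproductive_system", "embryo", "other")
    records: list[PhenotypeRecord] = []
    truth: list[str] = []
    for gene in sorted(genes):
        cat = cats[rng.choice(3, p=category_probs)]
        term = _PHENO_TEMPLATES[cat][rng.integers(len(_PHENO_TEMPLATES[cat]))]
        records.append(
            PhenotypeRecord(
                gene_id=gene,
                phenotype_term=term,
                category="other",
                accession=str(int(rng.integers(10_000, 3_000_000))),
            )
        )
        truth.append(cat)
    return records, truth


# ---------------------------------------------------------------------------
# Whole-study simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedStudy:
    """All four input tables for one synthetic study, with ground truth."""

    config: SyntheticConfig
    targets: list[TargetRecord]
    interactions: list[InteractionRecord]
    annotations: AnnotationSet
    phenotypes: list[PhenotypeRecord]
    truth_genes: set[str]              # genes passing the >90 score filter
    truth_edges: set[frozenset[str]]   # planted interaction edges
    truth_terms: list[str]             # planted enriched term ids
    truth_categories: list[str]        # per phenotype record
    planted_graph: GeneNetwork


def simulate_study(config: SyntheticConfig) -> SimulatedStudy:
    """Generate a coherent synthetic study: targets, interactions, annotations,
    phenotypes, and the ground truth connecting them.

    A fraction of the filter-passing genes is wired into one planted
    heavy-tailed component (the rest remain isolated, mimicking the
    many-singleton structure of the real network); annotations are planted
    over the hubs of that component.
    """
    rng = np.random.default_rng(config.seed)
    targets, truth_genes = generate_target_table(config)
    ordered = sorted(truth_genes)
    n_connected = max(3, int(round(config.connected_fraction * len(ordered))))
    connected_genes = [
        ordered[i] for i in rng.choice(len(ordered), size=n_connected, replace=False)
    ]

    if config.graph_model == "preferential_attachment":
        base = generate_preferential_attachment(
            n_connected, int(config.model_params.get("m", 2)), seed=int(rng.integers(2**31))
        )
    elif config.graph_model == "erdos_renyi":
        base = generate_erdos_renyi(
            n_connected, float(config.model_params.get("p", 0.005)),
            seed=int(rng.integers(2**31)),
        )
    else:
        raise ValueError(f"unknown graph model {config.graph_model!r}")
    relabel = dict(zip(sorted(base.graph.nodes), connected_genes))
    planted = GeneNetwork(
        graph=nx.relabel_nodes(base.graph, relabel), label="planted"
    )

    interactions, truth_edges = generate_interaction_table(
        planted,
        seed=int(rng.integers(2**31)),
        decoy_rate=config.decoy_rate,
        decoy_pool=set(ordered),
    )

    # hubs of the planted component, by the same ND > mu + sigma rule
    from .hubs import identify_hubs

    hub_genes = identify_hubs(planted).genes if planted.n_nodes >= 2 else set()
    annotations, truth_terms = generate_annotations(
        truth_genes,
        config.planted_terms,
        hub_genes,
        seed=int(rng.integers(2**31)),
        n_background_terms=config.n_background_terms,
        background_term_size=config.background_term_size,
        odds_ratio=config.planted_odds_ratio,
    )
    phenotypes, truth_categories = generate_phenotypes(
        sorted(hub_genes) if hub_genes else ordered[:20], seed=int(rng.integers(2**31))
    )
    return SimulatedStudy(
        config=config,
        targets=targets,
        interactions=interactions,
        annotations=annotations,
        phenotypes=phenotypes,
        truth_genes=truth_genes,
        truth_edges=truth_edges,
        truth_terms=truth_terms,
        truth_categories=truth_categories,
        planted_graph=planted,
    )


def write_study(study: SimulatedStudy, outdir) -> dict[str, str]:
    """Write the four input tables (+ ground-truth JSON) as TSV files."""
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    p = outdir / "targets.tsv"
    with p.open("w") as fh:
        fh.write("mirna\tgene\tscore\n")
        for r in study.targets:
            fh.write(f"{r.mirna_id}\t{r.gene_id}\t{r.score:.4f}\n")
    paths["targets"] = str(p)

    p = outdir / "interactions.tsv"
    with p.open("w") as fh:
        fh.write("gene_a\tgene_b\tcombined_score\n")
        for r in study.interactions:
            fh.write(f"{r.gene_a}\t{r.gene_b}\t{r.confidence:.4f}\n")
    paths["interactions"] = str(p)

    p = outdir / "annotations.tsv"
    with p.open("w") as fh:
        fh.write("term\tgene\n")
        for term in sorted(study.annotations.terms):
            for gene in sorted(study.annotations.terms[term]):
                fh.write(f"{term}\t{gene}\n")
    paths["annotations"] = str(p)

    p = outdir / "phenotypes.tsv"
    with p.open("w") as fh:
        fh.write("gene\tphenotype\taccession\n")
        for r in study.phenotypes:
            fh.write(f"{r.gene_id}\t{r.phenotype_term}\t{r.accession}\n")
    paths["phenotypes"] = str(p)

    p = outdir / "ground_truth.json"
    p.write_text(
        json.dumps(
            {
                "n_truth_genes": len(study.truth_genes),
                "n_truth_edges": len(study.truth_edges),
                "planted_terms": study.truth_terms,
                "truth_categories": study.truth_categories,
                "seed": study.config.seed,
            },
            indent=2,
        )
        + "\n"
    )
    paths["ground_truth"] = str(p)
    return paths
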