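"""Joining hub genes with mouse knockout-phenotype records.

Records are classified into the two study categories — reproductive-system
and embryo phenotypes — by a transparent, configurable keyword map applied
case-insensitively to the free-text phenotype term. An explicit category on
a record always wins over the keywords. The classified records are then
joined against the hub set, producing one table per category sorted by hub
degree (the "N of links" layout), plus the set of genes appearing in both.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import yaml

from .data_io import PhenotypeRecord, read_phenotype_table
from .hubs import HubSet

PHENOTYPE_JOIN_COLUMNS = ["gene_id", "degree", "categories", "phenotype_terms", "accession"]

# Category order matters: the first family with a match wins when a term
# would satisfy both.
DEFAULT_KEYWORDS: dict[str, list[str]] = {
    "reproductive_system": [
        "testis", "epididymis", "uterus", "ovary", "infertility",
        "seminal", "vagina", "oviduct", "sperm", "estrous",
    ],
    "embryo": [
        "embryo", "embryonic", "placenta", "neural tube", "yolk sac",
        "umbilical", "implantation",
    ],
}


@dataclass
class PhenotypeJoinRow:
    gene_id: str
    degree: int
    categories: frozenset[str]
    phenotype_terms: list[str]
    accession: str


def load_keywords(path: str | Path | None = None) -> dict[str, list[str]]:
    """Load a category → keyword-list map from YAML (default: shipped config)."""
    if path is None:
        text = resources.files("mirnome").joinpath("data/keywords.yaml").read_text()
    else:
        text = Path(path).read_text()
    loaded = yaml.safe_load(text)
    if not isinstance(loaded, dict):
        raise ValueError("keyword config must be a mapping category -> [keywords]")
    return {str(cat): [str(k) for k in kws] for cat, kws in loaded.items()}


def classify_phenotype_terms(
    records: list[PhenotypeRecord],
    keyword_config: dict[str, list[str]] | None = None,
) -> list[PhenotypeRecord]:
    """Fill in categories from phenotype-term keywords (case-insensitive).

    Records arriving with an explicit (non-``other``) category are left
    untouched; classification is idempotent.
    """
    keywords = keyword_config if keyword_config is not None else DEFAULT_KEYWORDS
    out: list[PhenotypeRecord] = []
    for rec in records:
        if rec.category != "other":
            out.append(rec)
            continue
        term = rec.phenotype_term.lower()
        category = "other"
        for cat, kws in keywords.items():
            if any(kw.lower() in term for kw in kws):
                category = cat
                break
        out.append(replace(rec, category=category) if category != "other" else rec)
    return out


def join_hubs_phenotypes(
    hubset: HubSet, records: list[PhenotypeRecord]
) -> tuple[list[PhenotypeJoinRow], list[PhenotypeJoinRow], set[str]]:
    """Cross-tabulate hub genes with classified KO-phenotype records.

    Returns (reproductive-system rows, embryo rows, genes in both), each
    table sorted by degree descending then gene id. Gene matching is
    case-insensitive; the hub capitalization is kept in output.
    """
    hub_by_key = {gene.casefold(): (gene, degree) for gene, degree in hubset.hubs}

    per_gene: dict[str, dict] = {}
    for rec in records:
        key = rec.gene_id.casefold()
        if key not in hub_by_key or rec.category == "other":
            continue
        gene, degree = hub_by_key[key]
        entry = per_gene.setdefault(
            key,
            {"gene": gene, "degree": degree, "categories": set(),
             "terms": {}, "accession": ""},
        )
        entry["categories"].add(rec.category)
        entry["terms"].setdefault(rec.category, []).append(rec.phenotype_term)
        if rec.accession and not entry["accession"]:
            entry["accession"] = rec.accession

    def table(category: str) -> list[PhenotypeJoinRow]:
        rows = [
            PhenotypeJoinRow(
                gene_id=e["gene"],
                degree=e["degree"],
                categories=frozenset(e["categories"]),
                phenotype_terms=list(e["terms"][category]),
                accession=e["accession"],
            )
            for e in per_gene.values()
            if category in e["categories"]
        ]
        rows.sort(key=lambda r: (-r.degree, r.gene_id))
        return rows

    reproductive = table("reproductive_system")
    embryo = table("embryo")
    both = {e["gene"] for e in per_gene.values() if len(e["categories"]) == 2}
    return reproductive, embryo, both


def load_ko_phenotype_fixture() -> list[PhenotypeRecord]:
    """Load the shipped KO-phenotype reference table (21 hub genes, 24 records)."""
    with resources.as_file(
        resources.files("mirnome").joinpath("data/ko_phenotypes.tsv")
    ) as path:
        return read_phenotype_table(path)


def fixture_hub_degrees() -> dict[str, int]:
    """Gene → "N of links" map of the shipped KO-phenotype reference table."""
    import pandas as pd

    with resources.as_file(
        resources.files("mirnome").joinpath("data/ko_phenotypes.tsv")
    ) as path:
        df = pd.read_csv(path, sep="\t")
    return {str(g): int(d) for g, d in zip(df["gene"], df["n_links"])}
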