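"""Hub identification by the degree-threshold rule ND > mu + sigma.

A hub is a node whose degree strictly exceeds the network's mean degree
plus one standard deviation of the degree sequence. The moments are those
of the analysed network itself (conventionally the main component), with
the standard deviation taken as the population value (the degree sequence
is the whole population, not a sample). Both conventions are switchable:
``inclusive=True`` relaxes the cut to >=, ``sample_sd=True`` uses the
(N-1)-denominator standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network_build import GeneNetwork
from .topology import degree_sequence


@dataclass
class HubSet:
    mu: float
    sigma: float
    threshold: float
    hubs: list[tuple[str, int]]  # (gene, degree), degree desc then gene
    hub_fraction: float          # percent of network nodes
    n_nodes: int

    @property
    def genes(self) -> set[str]:
        return {g for g, _ in self.hubs}


def identify_hubs(
    network: GeneNetwork, sample_sd: bool = False, inclusive: bool = False
) -> HubSet:
    """Apply ND > mu + sigma to the network's degree sequence."""
    if network.n_nodes < 2:
        raise ValueError("hub identification needs at least 2 nodes")
    degrees = degree_sequence(network)
    values = np.array(list(degrees.values()), dtype=float)
    mu = float(values.mean())
    sigma = float(values.std(ddof=1 if sample_sd else 0))
    threshold = mu + sigma
    passes = (lambda d: d >= threshold) if inclusive else (lambda d: d > threshold)
    hubs = sorted(
        ((g, d) for g, d in degrees.items() if passes(d)),
        key=lambda gd: (-gd[1], gd[0]),
    )
    return HubSet(
        mu=mu,
        sigma=sigma,
        threshold=threshold,
        hubs=hubs,
        hub_fraction=100.0 * len(hubs) / network.n_nodes,
        n_nodes=network.n_nodes,
    )


def hub_table(
    hubset: HubSet, provenance: dict[str, frozenset[str]] | None = None
) -> pd.DataFrame:
    """Tabulate hubs as (gene, degree, targeting miRNAs), degree descending.

    Mirrors the "N of links" layout of the KO-phenotype tables; ties in
    degree are ordered by gene id.
    """
    provenance = provenance or {}
    rows = [
        {
            "gene": gene,
            "degree": degree,
            "mirnas": ";".join(sorted(provenance.get(gene, frozenset()))),
        }
        for gene, degree in hubset.hubs
    ]
    return pd.DataFrame(rows, columns=["gene", "degree", "mirnas"])
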