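"""Per-miRNA network statistics: NOD, TFP and AGP.

NOD (novel out-degree) counts the targets a miRNA regulates exclusively —
genes whose in-degree in the scoring network is exactly 1. A high NOD marks
a miRNA sitting on weak, non-redundant regulatory sites. TFP is the
fraction of a miRNA's targets that are transcription-factor genes; AGP the
fraction belonging to a curated disease-associated gene list. TFP and AGP
are plain set-intersection fractions over the miRNA's target set and lie
in [0, 1].

NOD and TFP are scored on the disease-specific network; AGP defaults to
the full reference network (the disease gene list already carries the
disease specificity) but can be scored on the specific network instead.
"""

from __future__ import annotations

import pandas as pd

from .io import GeneSet, ValidationError
from .network import RegulatoryNetwork, targets

__all__ = ["nod", "tfp", "agp", "score_all"]


def nod(network: RegulatoryNetwork, mirna: str) -> int:
    """Count targets of ``mirna`` whose only regulator in ``network`` is it."""
    gene_set = targets(network, mirna)
    return sum(1 for g in gene_set.members if network.graph.in_degree(g) == 1)


def _fraction(network: RegulatoryNetwork, mirna: str, members: frozenset[str]) -> float:
    tgt = targets(network, mirna).members
    return len(tgt & members) / len(tgt)


def tfp(network: RegulatoryNetwork, mirna: str, tf_set: GeneSet) -> float:
    """Fraction of ``mirna``'s targets that are transcription-factor genes."""
    return _fraction(network, mirna, tf_set.members)


def agp(network: RegulatoryNetwork, mirna: str, disease_set: GeneSet) -> float:
    """Fraction of ``mirna``'s targets on the disease-associated gene list."""
    return _fraction(network, mirna, disease_set.members)


def score_all(
    specific: RegulatoryNetwork,
    reference: RegulatoryNetwork,
    tf_set: GeneSet,
    disease_set: GeneSet,
    agp_network: str = "reference",
) -> pd.DataFrame:
    """Score every miRNA of the disease-specific network.

    Returns a DataFrame indexed by miRNA ID (sorted) with columns ``nod``,
    ``tfp``, ``agp``. NOD/TFP use the specific network; AGP uses the
    network named by ``agp_network`` ("reference" or "specific").

    A miRNA present in the specific but not the reference network signals
    inconsistent inputs and is a hard error.
    """
    if agp_network not in ("reference", "specific"):
        raise ValueError(f"agp_network must be 'reference' or 'specific', got {agp_network!r}")
    agp_net = reference if agp_network == "reference" else specific
    mirnas = sorted(specific.mirna_nodes)
    missing = [m for m in mirnas if m not in reference.mirna_nodes]
    if missing:
        raise ValidationError(
            f"miRNA(s) in the specific but not the reference network: {missing[:5]}"
        )
    return pd.DataFrame(
        {
            "nod": [nod(specific, m) for m in mirnas],
            "tfp": [tfp(specific, m, tf_set) for m in mirnas],
            "agp": [agp(agp_net, m, disease_set) for m in mirnas],
        },
        index=pd.Index(mirnas, name="mirna_id"),
    )
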