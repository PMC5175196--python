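"""Synthetic study generation with planted ground truth.

Generates everything the pipeline reads — a two-group expression matrix,
interaction tables, TF / disease gene lists, and a literature-association
miRNA list — together with a truth manifest recording which differential
expression and which outlier miRNAs were planted, so recovery can be scored
without any external download.

The expression model is a positive, right-skewed array-intensity model:
log-normal baseline per gene, multiplicative log-normal within-group noise
with a chosen coefficient of variation, and planted DE genes whose
case-group mean is multiplied by the fold change (half up, half down). The
interaction model attaches background edges preferentially by gene
in-degree (heavy-tailed targeting, as in merged target databases) and
plants outlier miRNAs with a fixed number of exclusively regulated genes
and TF/disease-enriched target sets.

Three on-disk presets are provided: ``toy`` (a fixed, hand-checkable
8-miRNA / 20-gene study whose expected result at every pipeline stage is
recorded in its manifest), ``default`` (200 miRNAs, 1000 genes, the scale
used for recovery tests), and ``stress`` (2000 miRNAs, 5000 genes).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .io import CASE, CONTROL, ExpressionMatrix, InteractionSet, GeneSet

__all__ = [
    "simulate_expression",
    "simulate_network",
    "simulate_study",
    "write_manifest",
    "read_manifest",
    "TOY_EXPECTED",
]

PRESETS = ("toy", "default", "stress")


# ---------------------------------------------------------------------------
# expression

def _simulate_expression(
    rng: np.random.Generator,
    n_genes: int,
    n_case: int,
    n_control: int,
    n_de: int,
    fc: float,
    cv: float,
    gene_ids: list[str] | None = None,
    de_gene_ids: list[str] | None = None,
) -> tuple[ExpressionMatrix, dict[str, Any]]:
    if not (0 <= n_de <= n_genes):
        raise ValueError("need 0 <= n_de <= n_genes")
    if n_de > 0 and fc <= 1:
        raise ValueError("fold change must be > 1")
    if cv <= 0:
        raise ValueError("coefficient of variation must be > 0")
    if n_case < 2 or n_control < 2:
        raise ValueError("need >= 2 samples per group")
    if gene_ids is None:
        gene_ids = [f"G{i:05d}" for i in range(1, n_genes + 1)]
    if len(gene_ids) != n_genes:
        raise ValueError("gene_ids length mismatch")

    if de_gene_ids is None:
        de_gene_ids = list(rng.choice(gene_ids, size=n_de, replace=False))
    elif len(de_gene_ids) != n_de:
        raise ValueError("de_gene_ids length mismatch")
    de_set = {g: (fc if i % 2 == 0 else 1.0 / fc) for i, g in enumerate(de_gene_ids)}

    samples = [f"case_{i:03d}" for i in range(1, n_case + 1)] + [
        f"ctrl_{i:03d}" for i in range(1, n_control + 1)
    ]
    groups = pd.Series(
        [CASE] * n_case + [CONTROL] * n_control, index=samples, dtype=object
    )
    base = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=n_genes)
    factor = np.ones((n_genes, n_case + n_control))
    for i, g in enumerate(gene_ids):
        if g in de_set:
            factor[i, :n_case] = de_set[g]
    sigma = np.sqrt(np.log1p(cv**2))
    noise = rng.lognormal(
        mean=-sigma**2 / 2.0, sigma=sigma, size=(n_genes, n_case + n_control)
    )  # unit-mean noise: planted fold changes hold in expectation
    values = pd.DataFrame(
        base[:, None] * factor * noise, index=gene_ids, columns=samples
    )
    manifest = {
        "planted_de": {g: de_set[g] for g in sorted(de_set)},
        "params": {
            "n_genes": n_genes,
            "n_case": n_case,
            "n_control": n_control,
            "n_de": n_de,
            "fc": fc,
            "cv": cv,
        },
    }
    return ExpressionMatrix(values, groups), manifest


def simulate_expression(
    n_genes: int,
    n_case: int,
    n_control: int,
    n_de: int,
    fc: float,
    cv: float,
    seed: int,
    **kwargs,
) -> tuple[ExpressionMatrix, dict[str, Any]]:
    """Simulate a two-group expression matrix with ``n_de`` planted DE genes.

    Planted genes have their case-group mean multiplied by ``fc`` (even
    positions up, odd positions down by ``1/fc``); all values carry
    multiplicative log-normal noise with coefficient of variation ``cv``.
    Deterministic under ``seed``. Returns the matrix and a truth manifest.
    """
    rng = np.random.default_rng(seed)
    return _simulate_expression(rng, n_genes, n_case, n_control, n_de, fc, cv, **kwargs)


# ---------------------------------------------------------------------------
# interaction network

def _weighted_sample(
    rng: np.random.Generator, items: list[str], weights: np.ndarray, k: int
) -> list[str]:
    p = weights / weights.sum()
    idx = rng.choice(len(items), size=k, replace=False, p=p)
    return [items[i] for i in idx]


def _simulate_network(
    rng: np.random.Generator,
    n_mirna: int,
    n_gene: int,
    mean_degree: float,
    n_outliers: int,
    outlier_exclusive_targets: int,
    tf_frac: float,
    disease_frac: float,
    outlier_tf_boost: float,
    outlier_disease_boost: float,
) -> tuple[InteractionSet, GeneSet, GeneSet, dict[str, Any]]:
    if not (0 < tf_frac < 1 and 0 < disease_frac < 1):
        raise ValueError("tf_frac and disease_frac must lie in (0, 1)")
    if outlier_tf_boost < 1 or outlier_disease_boost < 1:
        raise ValueError("boost factors must be >= 1")
    n_reserved = n_outliers * outlier_exclusive_targets
    if n_reserved + max(10, int(mean_degree) + 1) > n_gene:
        raise ValueError(
            f"infeasible planting: {n_reserved} exclusive targets over {n_gene} genes"
        )

    genes = [f"G{i:05d}" for i in range(1, n_gene + 1)]
    mirnas = [f"miR-{i:04d}-5p" for i in range(1, n_mirna + 1)]
    tf_set = frozenset(rng.choice(genes, size=round(tf_frac * n_gene), replace=False))
    disease_set = frozenset(
        rng.choice(genes, size=round(disease_frac * n_gene), replace=False)
    )
    planted = sorted(rng.choice(mirnas, size=n_outliers, replace=False))

    # planted target sets are composition-stratified: a target set of size D
    # holds round(D * boost * frac) TF members and round(D * boost * frac)
    # disease members, i.e. the boosted fractions hold exactly rather than
    # only in expectation, so every planted outlier carries the designed
    # TFP/AGP enrichment
    p_tf = min(1.0, outlier_tf_boost * tf_frac)
    p_dis = min(1.0, outlier_disease_boost * disease_frac)

    def stratified_pick(
        k: int, pool: list[str], weights: np.ndarray | None, chosen: set[str]
    ) -> list[str]:
        avail = [g for g in pool if g not in chosen]
        if weights is None:
            w = np.ones(len(avail))
        else:
            wmap = dict(zip(pool, weights))
            w = np.array([wmap[g] for g in avail])
        k = min(k, len(avail))
        return _weighted_sample(rng, avail, w, k) if k else []

    def composed_targets(
        total: int, pools: dict[str, list[str]], weights, chosen: set[str]
    ) -> list[str]:
        n_tf = round(p_tf * total)
        n_dis = round(p_dis * total)
        picked: list[str] = []
        for k, pool_name in ((n_tf, "tf"), (n_dis, "dis"), (total, "rest")):
            k = k if pool_name != "rest" else total - len(picked)
            got = stratified_pick(k, pools[pool_name], weights.get(pool_name), chosen | set(picked))
            picked.extend(got)
        return picked[:total]

    # exclusive targets: withheld from all other attachment so their
    # in-degree stays exactly 1
    tf_pool = sorted(tf_set)
    dis_pool = sorted(disease_set - tf_set)
    rest_pool = sorted(set(genes) - tf_set - disease_set)
    reserved: set[str] = set()
    exclusive: dict[str, list[str]] = {}
    for m in planted:
        picks = composed_targets(
            outlier_exclusive_targets,
            {"tf": tf_pool, "dis": dis_pool, "rest": rest_pool},
            {},
            reserved,
        )
        exclusive[m] = sorted(picks)
        reserved.update(picks)
    free = [g for g in genes if g not in reserved]
    in_deg = {g: 0 for g in free}

    edges: set[tuple[str, str]] = set()
    planted_set = set(planted)
    for m in mirnas:
        deg = min(max(1, int(rng.poisson(mean_degree))), len(free))
        if m in planted_set:
            pools = {
                "tf": [g for g in free if g in tf_set],
                "dis": [g for g in free if g in disease_set and g not in tf_set],
                "rest": [g for g in free if g not in tf_set and g not in disease_set],
            }
            weights = {
                name: np.array([in_deg[g] + 1.0 for g in pool])
                for name, pool in pools.items()
            }
            picked = composed_targets(deg, pools, weights, set())
        else:
            w = np.array([in_deg[g] + 1.0 for g in free])
            picked = _weighted_sample(rng, free, w, deg)
        for g in picked:
            edges.add((m, g))
            in_deg[g] += 1
    for m, excl in exclusive.items():
        for g in excl:
            edges.add((m, g))

    pairs = sorted(edges)
    tags = rng.choice(["validated", "predicted"], size=len(pairs))
    records = pd.DataFrame(
        {
            "mirna": [p[0] for p in pairs],
            "gene": [p[1] for p in pairs],
            "sources": [frozenset([t]) for t in tags],
        }
    )
    interactions = InteractionSet(records)

    targets_of = {m: set() for m in mirnas}
    for m, g in pairs:
        targets_of[m].add(g)
    manifest = {
        "planted_outliers": {
            m: {
                "exclusive_targets": exclusive[m],
                "n_targets": len(targets_of[m]),
                "tf_fraction": len(targets_of[m] & tf_set) / len(targets_of[m]),
                "disease_fraction": len(targets_of[m] & disease_set) / len(targets_of[m]),
            }
            for m in planted
        },
        "params": {
            "n_mirna": n_mirna,
            "n_gene": n_gene,
            "mean_degree": mean_degree,
            "n_outliers": n_outliers,
            "outlier_exclusive_targets": outlier_exclusive_targets,
            "tf_frac": tf_frac,
            "disease_frac": disease_frac,
            "outlier_tf_boost": outlier_tf_boost,
            "outlier_disease_boost": outlier_disease_boost,
        },
    }
    return (
        interactions,
        GeneSet("tf", tf_set),
        GeneSet("disease", disease_set),
        manifest,
    )


def simulate_network(
    n_mirna: int,
    n_gene: int,
    mean_degree: float,
    n_outliers: int,
    outlier_exclusive_targets: int,
    tf_frac: float,
    disease_frac: float,
    outlier_tf_boost: float,
    outlier_disease_boost: float,
    seed: int,
) -> tuple[InteractionSet, GeneSet, GeneSet, dict[str, Any]]:
    """Simulate a bipartite interaction set with planted outlier miRNAs.

    Background edges attach preferentially by gene in-degree; each planted
    outlier receives ``outlier_exclusive_targets`` genes with no other
    regulator, and its whole target set is enriched for TF / disease genes
    by the boost factors. Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    return _simulate_network(
        rng,
        n_mirna,
        n_gene,
        mean_degree,
        n_outliers,
        outlier_exclusive_targets,
        tf_frac,
        disease_frac,
        outlier_tf_boost,
        outlier_disease_boost,
    )


# ---------------------------------------------------------------------------
# manifest I/O

def write_manifest(manifest: dict[str, Any], path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path: str | Path) -> dict[str, Any]:
    with open(Path(path)) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# on-disk studies

def _write_lines(path: Path, lines: list[str]) -> None:
    with open(path, "w") as fh:
        for line in lines:
            fh.write(line + "\n")


def _write_study(
    outdir: Path,
    matrix: ExpressionMatrix,
    interactions: InteractionSet,
    tf_set: GeneSet,
    disease_set: GeneSet,
    associated: list[str],
    manifest: dict[str, Any],
) -> dict[str, Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "annotation": outdir / "annotation.tsv",
        "interactions_validated": outdir / "interactions_validated.tsv",
        "interactions_predicted": outdir / "interactions_predicted.tsv",
        "tf_genes": outdir / "tf_genes.txt",
        "disease_genes": outdir / "disease_genes.txt",
        "associated_mirnas": outdir / "associated_mirnas.txt",
        "manifest": outdir / "manifest.json",
    }
    header = "gene_id\t" + "\t".join(matrix.sample_ids)
    rows = [
        g + "\t" + "\t".join(f"{v:.6f}" for v in matrix.values.loc[g])
        for g in sorted(matrix.gene_ids)
    ]
    _write_lines(paths["expression"], [header] + rows)
    _write_lines(
        paths["annotation"], [f"{s}\t{matrix.groups[s]}" for s in matrix.sample_ids]
    )
    validated, predicted = [], []
    for _, rec in interactions.records.iterrows():
        line_v = f"hsa-{rec['mirna']}\t{rec['gene']}\tvalidated"
        line_p = f"{rec['mirna']}\t{rec['gene']}\tpredicted"
        if "validated" in rec["sources"]:
            validated.append(line_v)
        if "predicted" in rec["sources"]:
            predicted.append(line_p)
    _write_lines(paths["interactions_validated"], sorted(validated))
    _write_lines(paths["interactions_predicted"], sorted(predicted))
    _write_lines(paths["tf_genes"], sorted(tf_set.members))
    _write_lines(paths["disease_genes"], sorted(disease_set.members))
    _write_lines(paths["associated_mirnas"], sorted(associated))
    write_manifest(manifest, paths["manifest"])
    return paths


# --- fixed toy study -------------------------------------------------------
# An 8-miRNA / 20-gene study small enough to check every stage by hand:
# miR-t1 regulates 5 exclusive DE genes (NOD 5), miR-t2 and miR-t3 four each
# (NOD 4), miR-t4..t8 share one DE hub gene (NOD 0); the association list
# holds miR-t1, miR-t2 and a decoy, and the AGP ordering puts miR-t1 first.

_TOY_MIRNAS = [f"miR-t{i}" for i in range(1, 9)]
_TOY_GENES = [f"G{i:02d}" for i in range(1, 21)]

_TOY_SPECIFIC_EDGES = (
    [("miR-t1", f"G{i:02d}") for i in range(1, 6)]
    + [("miR-t2", f"G{i:02d}") for i in range(6, 10)]
    + [("miR-t3", f"G{i:02d}") for i in range(10, 14)]
    + [(f"miR-t{i}", "G16") for i in range(4, 9)]
)
_TOY_REFERENCE_ONLY_EDGES = [
    ("miR-t1", "G17"),
    ("miR-t2", "G18"),
    ("miR-t5", "G19"),
    ("miR-t6", "G19"),
    ("miR-t7", "G20"),
    ("miR-t8", "G20"),
]
_TOY_TF = ["G01", "G02", "G06", "G07", "G10", "G11"]
_TOY_DISEASE = ["G01", "G02", "G03", "G06", "G07", "G10"]
_TOY_ASSOCIATED = ["miR-t1", "miR-t2", "miR-t6"]

#: Hand-derived expected result of every pipeline stage on the toy study.
#: Scores are exact arithmetic; p-values are the tie-corrected normal
#: approximation of the signed-rank outlier test, cross-checked against an
#: independent implementation before freezing.
TOY_EXPECTED: dict[str, Any] = {
    "de_genes": [f"G{i:02d}" for i in range(1, 17)],
    "reference_counts": {"mirnas": 8, "genes": 18, "edges": 24},
    "specific_counts": {"mirnas": 8, "genes": 14, "edges": 18},
    "nod": {"miR-t1": 5, "miR-t2": 4, "miR-t3": 4,
            **{f"miR-t{i}": 0 for i in range(4, 9)}},
    "tfp": {"miR-t1": 0.4, "miR-t2": 0.5, "miR-t3": 0.5,
            **{f"miR-t{i}": 0.0 for i in range(4, 9)}},
    "agp": {"miR-t1": 0.5, "miR-t2": 0.4, "miR-t3": 0.25,
            **{f"miR-t{i}": 0.0 for i in range(4, 9)}},
    "nod_p": {"miR-t1": 0.008831121861723294, "miR-t2": 0.022750131948179195,
              "miR-t3": 0.022750131948179195},
    "tfp_p": {"miR-t1": 0.03249157225410538, "miR-t2": 0.013134145691021117,
              "miR-t3": 0.013134145691021117},
    "agp_p": {"miR-t1": 0.00894089877045475, "miR-t2": 0.014166481392405119},
    "nod_survivors": ["miR-t1", "miR-t2", "miR-t3"],
    "tfp_survivors": ["miR-t2", "miR-t3", "miR-t1"],
    "association_survivors": ["miR-t2", "miR-t1"],
    "candidates": ["miR-t1", "miR-t2"],
}


def _toy_study() -> tuple[ExpressionMatrix, InteractionSet, GeneSet, GeneSet, list[str], dict]:
    ctrl_pattern = np.array([1.00, 1.04, 0.96, 1.00])
    null_case_pattern = np.array([1.01, 1.05, 0.97, 0.99])
    rows = []
    planted_de: dict[str, float] = {}
    for i, g in enumerate(_TOY_GENES, start=1):
        base = 8.0 + i
        if i <= 8:  # up-regulated DE
            case, fc = base * 4.0 * ctrl_pattern, 4.0
        elif i <= 16:  # down-regulated DE
            case, fc = base * 0.25 * ctrl_pattern, 0.25
        else:  # null genes
            case, fc = base * null_case_pattern, None
        if fc is not None:
            planted_de[g] = fc
        rows.append(np.concatenate([case, base * ctrl_pattern]))
    samples = [f"case_{i:03d}" for i in range(1, 5)] + [f"ctrl_{i:03d}" for i in range(1, 5)]
    matrix = ExpressionMatrix(
        pd.DataFrame(rows, index=_TOY_GENES, columns=samples),
        pd.Series([CASE] * 4 + [CONTROL] * 4, index=samples, dtype=object),
    )
    all_edges = sorted(_TOY_SPECIFIC_EDGES + _TOY_REFERENCE_ONLY_EDGES)
    # first specific edge of each miRNA appears in both source files to
    # exercise cross-file deduplication
    dup = {min(e for e in all_edges if e[0] == m) for m in _TOY_MIRNAS}
    records = pd.DataFrame(
        {
            "mirna": [m for m, _ in all_edges],
            "gene": [g for _, g in all_edges],
            "sources": [
                frozenset(["validated", "predicted"]) if e in dup else frozenset(["validated"])
                for e in all_edges
            ],
        }
    )
    interactions = InteractionSet(records)
    manifest = {
        "preset": "toy",
        "planted_de": planted_de,
        "planted_outliers": {
            "miR-t1": {"exclusive_targets": [f"G{i:02d}" for i in range(1, 6)]},
            "miR-t2": {"exclusive_targets": [f"G{i:02d}" for i in range(6, 10)]},
            "miR-t3": {"exclusive_targets": [f"G{i:02d}" for i in range(10, 14)]},
        },
        "expected": TOY_EXPECTED,
    }
    return (
        matrix,
        interactions,
        GeneSet("tf", frozenset(_TOY_TF)),
        GeneSet("disease", frozenset(_TOY_DISEASE)),
        list(_TOY_ASSOCIATED),
        manifest,
    )


_DEFAULT_NET = dict(
    n_mirna=200, n_gene=1000, mean_degree=8.0, n_outliers=10,
    outlier_exclusive_targets=6, tf_frac=0.1, disease_frac=0.1,
    outlier_tf_boost=3.0, outlier_disease_boost=3.0,
)
_DEFAULT_EXPR = dict(n_case=20, n_control=20, n_de=300, fc=4.0, cv=0.2)
_STRESS_NET = dict(_DEFAULT_NET, n_mirna=2000, n_gene=5000, n_outliers=20)
_STRESS_EXPR = dict(_DEFAULT_EXPR, n_de=1000)
_N_ASSOC_DECOYS = 20


def _random_study(net_params: dict, expr_params: dict, seed: int):
    rng = np.random.default_rng(seed)
    interactions, tf_set, disease_set, net_manifest = _simulate_network(rng, **net_params)
    planted = sorted(net_manifest["planted_outliers"])
    # planted outliers' targets are forced DE so they survive network trimming
    forced = sorted(
        {g for m, g in interactions.pairs() if m in set(planted)}
    )
    n_gene = net_params["n_gene"]
    gene_ids = [f"G{i:05d}" for i in range(1, n_gene + 1)]
    n_de = expr_params["n_de"]
    if len(forced) > n_de:
        raise ValueError("n_de too small for planted outlier targets")
    others = [g for g in gene_ids if g not in set(forced)]
    extra = sorted(rng.choice(others, size=n_de - len(forced), replace=False))
    de_gene_ids = forced + extra
    matrix, expr_manifest = _simulate_expression(
        rng,
        n_genes=n_gene,
        n_case=expr_params["n_case"],
        n_control=expr_params["n_control"],
        n_de=n_de,
        fc=expr_params["fc"],
        cv=expr_params["cv"],
        gene_ids=gene_ids,
        de_gene_ids=de_gene_ids,
    )
    decoys = sorted(
        rng.choice(
            [m for m in sorted(interactions.mirnas) if m not in set(planted)],
            size=_N_ASSOC_DECOYS,
            replace=False,
        )
    )
    associated = sorted(planted + decoys)
    manifest = {
        "planted_de": expr_manifest["planted_de"],
        "planted_outliers": net_manifest["planted_outliers"],
        "association_decoys": decoys,
        "params": {
            "network": net_manifest["params"],
            "expression": expr_manifest["params"],
            "seed": seed,
        },
    }
    return matrix, interactions, tf_set, disease_set, associated, manifest


def simulate_study(preset: str, seed: int, outdir: str | Path) -> dict[str, Path]:
    """Write a full on-disk study (all pipeline inputs plus truth manifest).

    ``toy`` is a fixed, hand-checkable fixture and is byte-identical across
    runs regardless of ``seed``; ``default`` and ``stress`` are seeded
    random studies. Returns the mapping of input names to file paths.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    outdir = Path(outdir)
    if preset == "toy":
        parts = _toy_study()
    elif preset == "default":
        parts = _random_study(_DEFAULT_NET, _DEFAULT_EXPR, seed)
        parts[5]["preset"] = "default"
    else:
        parts = _random_study(_STRESS_NET, _STRESS_EXPR, seed)
        parts[5]["preset"] = "stress"
    return _write_study(outdir, *parts)
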