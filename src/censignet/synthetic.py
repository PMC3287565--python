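"""Seeded synthetic inputs with the statistical structure the method assumes.

Three generators emulate the three real input classes:

* a *signature collection* of ~100 gene sets of heterogeneous size drawn
  from a gene pool, with a small recurrent "core" subset that enters each
  signature independently with a fixed probability — reproducing the
  low-overlap regime (most genes in few signatures, a core in many);
* an *interactome* with hub-heavy degree structure (preferential-attachment
  backbone) carrying a planted densely connected module on the core genes,
  so that centrality rankings have a known ground truth to recover;
* a two-group *expression dataset* in which the signature genes are shifted
  in one group, with clinical attributes (a binary receptor-status analog
  and numeric outcome analogs) correlated with group membership.

Everything is driven by ``numpy.random.default_rng`` seeded from
``(seed, stream-tag)``; identical spec + seed gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from censignet.network import InteractionNetwork, write_edge_list
from censignet.signatures import SignatureCollection, write_gmt
from censignet.validation import ExpressionDataset, write_expression

# stream tags keep the three generators' randomness independent
_SIG_STREAM, _PIN_STREAM, _EXPR_STREAM = 11, 22, 33


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    Defaults are sized for fast desk-scale runs: 100 signatures over a
    5000-gene pool with 50 core genes, a 2000-node interactome carrying a
    40-gene planted module, and a 60+60-sample expression matrix.
    """

    seed: int = 0
    n_signatures: int = 100
    signature_size_range: tuple[int, int] = (4, 3000)
    core_gene_count: int = 50
    core_inclusion_prob: float = 0.3
    background_pool_size: int = 5000
    pin_nodes: int = 2000
    attachment: int = 4
    module_size: int = 40
    module_edge_prob: float = 1.0
    samples_per_group: int = 60
    effect_size: float = 5.0
    noise_sd: float = 1.0
    clinical_association_prob: float = 0.9
    n_expression_background_genes: int = 460

    def __post_init__(self) -> None:
        lo, hi = self.signature_size_range
        if not (1 <= lo <= hi):
            raise ValueError(f"bad signature size range {self.signature_size_range}")
        for name in (
            "n_signatures", "core_gene_count", "background_pool_size",
            "pin_nodes", "attachment", "module_size", "samples_per_group",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in (
            "core_inclusion_prob", "module_edge_prob", "clinical_association_prob",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.core_gene_count > self.background_pool_size:
            raise ValueError("core_gene_count exceeds the gene pool size")
        if self.pin_nodes > self.background_pool_size:
            raise ValueError("pin_nodes exceeds the gene pool size")
        if self.module_size > self.pin_nodes:
            raise ValueError("module_size exceeds pin_nodes")
        if hi > self.background_pool_size:
            raise ValueError("largest signature size exceeds the gene pool")
        if self.effect_size < 0 or self.noise_sd <= 0:
            raise ValueError("effect_size must be >= 0 and noise_sd > 0")

    # -- gene naming: one pool, core genes first (also the oldest, hub-prone
    #    interactome nodes), background after ------------------------------
    def gene_name(self, i: int) -> str:
        return f"GENE{i:05d}"

    @property
    def pool_genes(self) -> list[str]:
        return [self.gene_name(i) for i in range(self.background_pool_size)]

    @property
    def core_genes(self) -> list[str]:
        return [self.gene_name(i) for i in range(self.core_gene_count)]

    @property
    def module_genes(self) -> list[str]:
        return [self.gene_name(i) for i in range(self.module_size)]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["signature_size_range"] = list(self.signature_size_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        if "signature_size_range" in d:
            d["signature_size_range"] = tuple(d["signature_size_range"])
        return cls(**d)


def _rng(spec: SyntheticSpec, stream: int, seed: int | None) -> np.random.Generator:
    return np.random.default_rng([spec.seed if seed is None else seed, stream])


def generate_signature_collection(
    spec: SyntheticSpec, seed: int | None = None
) -> SignatureCollection:
    """Draw ``n_signatures`` gene sets of log-uniform size from the pool.

    Each core gene enters a signature independently with
    ``core_inclusion_prob``; remaining slots are filled without replacement
    from the non-core background.  Signature sizes therefore vary over
    orders of magnitude while the core recurs across signatures.
    """
    rng = _rng(spec, _SIG_STREAM, seed)
    lo, hi = spec.signature_size_range
    n_core = spec.core_gene_count
    background = np.arange(n_core, spec.background_pool_size)
    signatures: dict[str, frozenset[str]] = {}
    labels: dict[str, str] = {}
    for i in range(spec.n_signatures):
        size = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
        size = max(lo, min(hi, size))
        core_in = np.flatnonzero(rng.random(n_core) < spec.core_inclusion_prob)
        n_fill = min(max(size - core_in.size, 0), background.size)
        fill = rng.choice(background, size=n_fill, replace=False)
        idx = np.concatenate([core_in, fill])
        if idx.size == 0:  # possible only with core_prob 0 and size 0 fill
            idx = rng.choice(background, size=1, replace=False)
        name = f"SIG{i + 1:03d}"
        signatures[name] = frozenset(spec.gene_name(j) for j in idx)
        labels[name] = "synthetic signature"
    return SignatureCollection(signatures=signatures, source_labels=labels)


def generate_pin(spec: SyntheticSpec, seed: int | None = None) -> InteractionNetwork:
    """Preferential-attachment backbone plus a planted dense module.

    The backbone is a Barabasi-Albert graph (``attachment`` edges per new
    node), giving the hub-heavy tail of real interactomes.  Nodes are
    labelled core genes first — the earliest, hub-prone attachment
    positions — then background genes.  The first ``module_size`` genes
    additionally have each internal pair connected with
    ``module_edge_prob``, planting a recoverable dense module.
    """
    rng = _rng(spec, _PIN_STREAM, seed)
    nx_seed = int(rng.integers(0, 2**31 - 1))
    g = nx.barabasi_albert_graph(spec.pin_nodes, spec.attachment, seed=nx_seed)
    for a in range(spec.module_size):
        for b in range(a + 1, spec.module_size):
            if rng.random() < spec.module_edge_prob:
                g.add_edge(a, b)
    g = nx.relabel_nodes(g, {i: spec.gene_name(i) for i in range(spec.pin_nodes)})
    net = InteractionNetwork(graph=g, name="synthetic_pin")
    net.assert_simple()
    return net


def generate_expression(
    spec: SyntheticSpec,
    signature_genes: list[str] | None = None,
    seed: int | None = None,
) -> ExpressionDataset:
    """Two-group expression matrix with group-correlated clinical attributes.

    Baseline intensities are i.i.d. Normal(8, ``noise_sd``); the signature
    genes (default: the planted module) are shifted by ``effect_size`` in
    group 2 only.  Clinical attributes: ``group`` (ground truth, 1/2);
    ``er_status`` equal to the group-1 indicator with probability
    ``clinical_association_prob`` (else flipped); ``age``, ``npi_score``
    and ``time_to_metastasis_days`` drawn from group-dependent normals so
    that group 1 resembles the better-outcome cluster.
    """
    rng = _rng(spec, _EXPR_STREAM, seed)
    if signature_genes is None:
        signature_genes = spec.module_genes
    sig = list(dict.fromkeys(g.strip().upper() for g in signature_genes))
    genes = sig + [f"EXPR{i:04d}" for i in range(spec.n_expression_background_genes)]
    n = spec.samples_per_group
    samples = [f"S{i + 1:03d}" for i in range(2 * n)]
    group = np.array([1] * n + [2] * n)

    x = rng.normal(8.0, spec.noise_sd, size=(len(genes), 2 * n))
    x[: len(sig), n:] += spec.effect_size
    expr = pd.DataFrame(x, index=genes, columns=samples)

    is_g1 = (group == 1).astype(int)
    keep = rng.random(2 * n) < spec.clinical_association_prob
    er = np.where(keep, is_g1, 1 - is_g1)
    clinical = pd.DataFrame(
        {
            "group": group,
            "er_status": er,
            "age": np.round(rng.normal(np.where(group == 1, 47.0, 45.0), 9.0), 1),
            "npi_score": np.round(
                rng.normal(np.where(group == 1, 3.4, 4.17), 1.0), 2
            ),
            "time_to_metastasis_days": np.round(
                rng.normal(np.where(group == 1, 3000.0, 2600.0), 1200.0), 0
            ),
        },
        index=pd.Index(samples, name="sample"),
    )
    return ExpressionDataset(expression=expr, clinical=clinical)


def write_synthetic_inputs(
    spec: SyntheticSpec, out_dir: str | Path, seed: int | None = None
) -> dict[str, Path]:
    """Generate and write all synthetic inputs; returns the file paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "signatures": out / "signatures.gmt",
        "network": out / "network.tsv",
        "expression": out / "expression.tsv",
        "clinical": out / "clinical.tsv",
        "module": out / "planted_module.txt",
    }
    write_gmt(generate_signature_collection(spec, seed), paths["signatures"])
    write_edge_list(generate_pin(spec, seed), paths["network"])
    data = generate_expression(spec, seed=seed)
    write_expression(data.expression, paths["expression"])
    data.clinical.to_csv(paths["clinical"], sep="\t", lineterminator="\n")
    paths["module"].write_text("\n".join(spec.module_genes) + "\n", encoding="utf-8")
    return paths
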