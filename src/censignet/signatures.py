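"""Gene-signature collections: GMT parsing, support counting and filtering.

A signature is a named set of gene symbols whose joint expression pattern is
associated with a phenotype.  Published signatures for the same disease
typically share very few genes, so the first integration step counts, for
every gene, the number of signatures that contain it (its *support*) and
discards genes supported by a single signature only.
"""

from __future__ import annotations

import logging
import statistics
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)


class GMTParseError(ValueError):
    """Raised for a malformed GMT line (fewer than 3 tab-separated fields)."""


@dataclass
class SignatureCollection:
    """An ordered map of signature id -> set of uppercase gene symbols.

    Gene symbols are normalized to uppercase with surrounding whitespace
    stripped; within a signature each gene appears once.  ``source_labels``
    optionally carries free-text provenance (the GMT description column).
    """

    signatures: dict[str, frozenset[str]]
    source_labels: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.signatures)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignatureCollection):
            return NotImplemented
        return self.signatures == other.signatures

    def all_genes(self) -> frozenset[str]:
        """Union of every signature's gene set."""
        out: set[str] = set()
        for genes in self.signatures.values():
            out |= genes
        return frozenset(out)

    def sizes(self) -> list[int]:
        return [len(g) for g in self.signatures.values()]


@dataclass(frozen=True)
class GeneFrequencyTable:
    """Per-gene count of signatures containing the gene (support)."""

    frequency: Mapping[str, int]

    def __getitem__(self, gene: str) -> int:
        return self.frequency[gene]

    def __len__(self) -> int:
        return len(self.frequency)


@dataclass(frozen=True)
class OverlapHistogram:
    """Number of genes at each exact support value.

    ``counts[f]`` is the number of genes found in exactly ``f`` signatures;
    ``total_genes`` is the number of distinct genes overall (the sum of the
    counts).
    """

    counts: Mapping[int, int]
    total_genes: int

    def genes_with_support_at_least(self, min_support: int) -> int:
        """Number of genes found in ``min_support`` or more signatures."""
        return sum(c for f, c in self.counts.items() if f >= min_support)

    def fraction_at(self, support: int) -> float:
        """Fraction (0..1) of all genes at exactly this support value."""
        if self.total_genes == 0:
            return 0.0
        return self.counts.get(support, 0) / self.total_genes


@dataclass(frozen=True)
class CollectionSummary:
    n_signatures: int
    min_size: int
    median_size: float
    max_size: int


def _normalize_symbol(token: str) -> str:
    return token.strip().upper()


def read_gmt(path: str | Path) -> SignatureCollection:
    """Read a signature collection from a GMT file.

    Each line: ``name<TAB>description<TAB>gene1<TAB>gene2...``.  Duplicate
    genes within a line are collapsed, empty gene tokens dropped, symbols
    uppercased.  The description column is metadata and never parsed as a
    gene.

    Raises
    ------
    GMTParseError
        For a line with fewer than 3 fields (naming the line number).
    ValueError
        For a duplicate signature id.
    """
    path = Path(path)
    signatures: dict[str, frozenset[str]] = {}
    labels: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, description = fields[0].strip(), fields[1]
            if name in signatures:
                raise ValueError(f"{path}:{lineno}: duplicate signature id {name!r}")
            genes = frozenset(
                _normalize_symbol(t) for t in fields[2:] if t.strip()
            )
            if not genes:
                raise GMTParseError(f"{path}:{lineno}: signature {name!r} has no genes")
            signatures[name] = genes
            labels[name] = description
    return SignatureCollection(signatures=signatures, source_labels=labels)


def write_gmt(collection: SignatureCollection, path: str | Path) -> None:
    """Write a collection to GMT with sorted gene columns (stable diffs)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for name, genes in collection.signatures.items():
            desc = collection.source_labels.get(name, "na") or "na"
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def gene_frequencies(collection: SignatureCollection) -> GeneFrequencyTable:
    """Count, for every gene, the number of signatures containing it."""
    if len(collection) == 0:
        raise ValueError("empty signature collection")
    counter: Counter[str] = Counter()
    for genes in collection.signatures.values():
        counter.update(genes)
    return GeneFrequencyTable(frequency=dict(counter))


def filter_min_support(
    freq: GeneFrequencyTable, min_support: int = 2
) -> set[str]:
    """Genes supported by at least ``min_support`` signatures.

    ``min_support=2`` implements the default rule that a gene seen in only
    one signature may be there by chance and is discarded.
    """
    if min_support < 1:
        raise ValueError(f"min_support must be >= 1, got {min_support}")
    kept = {g for g, f in freq.frequency.items() if f >= min_support}
    logger.info(
        "min-support filter (>=%d): kept %d of %d genes",
        min_support, len(kept), len(freq),
    )
    return kept


def overlap_histogram(freq: GeneFrequencyTable) -> OverlapHistogram:
    """Histogram of support values: how many genes occur in exactly f signatures."""
    counts: Counter[int] = Counter(freq.frequency.values())
    return OverlapHistogram(counts=dict(counts), total_genes=len(freq))


def collection_summary(collection: SignatureCollection) -> CollectionSummary:
    """Signature count and min/median/max sizes (after within-set dedup).

    Median uses the mean-of-two-middle convention for even counts.
    """
    if len(collection) == 0:
        raise ValueError("empty signature collection")
    sizes = collection.sizes()
    return CollectionSummary(
        n_signatures=len(sizes),
        min_size=min(sizes),
        median_size=float(statistics.median(sizes)),
        max_size=max(sizes),
    )


def write_frequency_table(freq: GeneFrequencyTable, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\tn_signatures\n")
        for gene in sorted(freq.frequency):
            fh.write(f"{gene}\t{freq.frequency[gene]}\n")


def write_histogram(hist: OverlapHistogram, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("frequency\tn_genes\n")
        for f in sorted(hist.counts):
            fh.write(f"{f}\t{hist.counts[f]}\n")


def frequency_table_from_histogram(
    counts: Mapping[int, int], prefix: str = "G"
) -> GeneFrequencyTable:
    """Expand a support histogram into a synthetic per-gene frequency table.

    Useful for recomputing summary statistics when only the histogram (not
    the underlying gene lists) is available; gene names are placeholders.
    """
    freq: dict[str, int] = {}
    i = 0
    for f in sorted(counts):
        if f < 1:
            raise ValueError(f"support values must be >= 1, got {f}")
        for _ in range(counts[f]):
            freq[f"{prefix}{i:06d}"] = f
            i += 1
    return GeneFrequencyTable(frequency=freq)


def apply_synonyms(
    collection: SignatureCollection, synonyms: Mapping[str, str]
) -> SignatureCollection:
    """Rewrite gene symbols through a user-supplied synonym map.

    Keys and values are uppercased; unmapped symbols pass through.  Sets are
    re-deduplicated after mapping.
    """
    table = {k.upper(): v.upper() for k, v in synonyms.items()}
    new = {
        name: frozenset(table.get(g, g) for g in genes)
        for name, genes in collection.signatures.items()
    }
    return SignatureCollection(signatures=new, source_labels=dict(collection.source_labels))
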