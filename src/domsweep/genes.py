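"""Gene models: coordinates, strand, TSS/TTS, exon structure, GFF3 round-trip.

Coordinates follow GFF3 conventions internally: 1-based, inclusive
``start``/``end`` with ``start <= end`` regardless of strand.  The TSS is
``start`` for ``+`` genes and ``end`` for ``-`` genes; the TTS is the other
end.  Promoter/upstream intervals are emitted 0-based half-open (BED).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Gene", "GeneModelSet", "read_gff3", "write_gff3"]


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # "+" or "-"
    exons: tuple  # ((start, end), ...) 1-based inclusive, ordered, non-overlapping

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.start > self.end:
            raise ValueError("start > end")
        prev_end = None
        for s, e in self.exons:
            if s < self.start or e > self.end or s > e:
                raise ValueError(f"exon ({s},{e}) outside gene span of {self.gene_id}")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"exons overlap/unordered in {self.gene_id}")
            prev_end = e

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        return self.end if self.strand == "+" else self.start

    def upstream_interval(self, flank: int) -> tuple[int, int]:
        """Strand-aware upstream interval, 0-based half-open, clipped at 0.

        For a + gene with TSS t this is [t-1-flank, t-1); for a - gene
        [t, t+flank).  The TSS base itself is not part of the interval.
        """
        if self.strand == "+":
            return max(0, self.tss - 1 - flank), self.tss - 1
        return self.tss, self.tss + flank

    def downstream_interval(self, flank: int) -> tuple[int, int]:
        if self.strand == "+":
            return self.tts, self.tts + flank
        return max(0, self.tts - 1 - flank), self.tts - 1

    def body_interval(self) -> tuple[int, int]:
        """Gene span, 0-based half-open."""
        return self.start - 1, self.end


class GeneModelSet:
    """An ordered collection of :class:`Gene` with interval queries."""

    def __init__(self, genes: list[Gene]):
        self.genes = sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))
        self._by_id = {g.gene_id: g for g in self.genes}
        if len(self._by_id) != len(self.genes):
            raise ValueError("duplicate gene ids")

    def __len__(self):
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def chroms(self) -> list[str]:
        seen = dict.fromkeys(g.chrom for g in self.genes)
        return list(seen)

    def on_chrom(self, chrom: str) -> list[Gene]:
        return [g for g in self.genes if g.chrom == chrom]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "chrom": [g.chrom for g in self.genes],
                "start": [g.start for g in self.genes],
                "end": [g.end for g in self.genes],
                "strand": [g.strand for g in self.genes],
                "tss": [g.tss for g in self.genes],
                "tts": [g.tts for g in self.genes],
                "n_exons": [len(g.exons) for g in self.genes],
            }
        )

    def promoter_bed(self, flank: int = 2000) -> pd.DataFrame:
        """Upstream intervals as BED6 (0-based half-open)."""
        rows = []
        for g in self.genes:
            s, e = g.upstream_interval(flank)
            rows.append((g.chrom, s, e, g.gene_id, 0, g.strand))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def write_gff3(genes: GeneModelSet, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tdomsweep\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tdomsweep\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for k, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tdomsweep\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna}.exon{k};Parent={mrna}\n"
                )


def read_gff3(path: str) -> GeneModelSet:
    """Load gene/exon features from a GFF3 file (gffutils-backed)."""
    import gffutils

    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene"):
        exons = []
        for child in db.children(feat, featuretype="exon", order_by="start"):
            exons.append((child.start, child.end))
        if not exons:
            exons = [(feat.start, feat.end)]
        genes.append(
            Gene(
                gene_id=feat.id,
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                exons=tuple(exons),
            )
        )
    return GeneModelSet(genes)
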