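"""Gene content of detected regions and homology-table summaries.

Genes are counted into regions by any-overlap (>= 1 bp), the convention for
"gene predictions overlapping the regions"; an optional minimum-overlap
fraction tightens this. All biotypes count, not only protein-coding genes.
Homology is consumed as a flat TSV export (gene_id, homolog_species,
homolog_id, one_to_one); live database queries are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .intervals import GenomicInterval, merge_intervals, subtract


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene: id, span, biotype, optional exon structure."""

    gene_id: str
    interval: GenomicInterval
    biotype: str = "protein_coding"
    exons: tuple[GenomicInterval, ...] = ()


def genes_in_regions(
    annotation: Sequence[GeneRecord],
    regions: Sequence[GenomicInterval],
    min_overlap_frac: float = 0.0,
) -> list[GeneRecord]:
    """Genes overlapping any region; each gene counted once.

    ``min_overlap_frac`` (of the gene's length) defaults to 0, i.e. a single
    shared base pair suffices.
    """
    out = []
    for g in annotation:
        need = max(1, int(min_overlap_frac * g.interval.length()))
        if any(g.interval.overlap(r) >= need for r in regions):
            out.append(g)
    return out


def read_homology_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"one_to_one": bool})
    required = {"gene_id", "homolog_species", "homolog_id", "one_to_one"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"homology table missing columns: {sorted(missing)}")
    oto = df[df["one_to_one"]]
    if oto.duplicated(["gene_id", "homolog_species"]).any():
        raise ValueError("duplicate one-to-one rows for a (gene, species) pair")
    return df


def homology_summary(
    genes: Sequence[GeneRecord], homology: pd.DataFrame, species: str
) -> tuple[int, int, int]:
    """(n_genes, n_with_homolog, n_one_to_one) for one homolog species.

    Counts are per distinct gene, so n_one_to_one <= n_hom <= n_genes holds
    by construction — a summary violating it indicates a malformed upstream
    export.
    """
    ids = {g.gene_id for g in genes}
    sub = homology[
        homology["gene_id"].isin(ids) & (homology["homolog_species"] == species)
    ]
    n_hom = sub["gene_id"].nunique()
    n_oto = sub.loc[sub["one_to_one"], "gene_id"].nunique()
    assert n_oto <= n_hom <= len(ids)
    return len(ids), n_hom, n_oto


def retrogene_flag(
    gene: GeneRecord, regions: Sequence[GenomicInterval]
) -> bool | None:
    """Retrogene-insertion pattern: all exons in regions, some intron out.

    A processed retrogene copied into the sampled chromosome shows exactly
    this signature — exonic sequence present, intronic absent. Returns
    ``None`` when the gene carries no exon structure (not applicable), and
    ``False`` for single-exon genes (no intron to test).
    """
    if not gene.exons:
        return None
    merged = merge_intervals(list(gene.exons))
    introns = subtract(gene.interval, merged)
    if not introns:
        return False
    all_exons_in = all(
        any(e.overlap(r) > 0 for r in regions) for e in merged
    )
    some_intron_out = any(
        all(i.overlap(r) == 0 for r in regions) for i in introns
    )
    return all_exons_in and some_intron_out


def gene_content_table(
    per_sample: dict[str, tuple[str, Sequence[GenomicInterval], Sequence[GeneRecord]]],
    homology: pd.DataFrame | None = None,
    species: str = "human",
) -> pd.DataFrame:
    """Per-species gene statistics: region bp, gene count, homolog counts.

    ``per_sample`` maps sample → (reference name, consensus regions, genes
    already restricted to those regions).
    """
    from .intervals import total_size

    rows = []
    for sample, (reference, regions, genes) in per_sample.items():
        n_genes = len({g.gene_id for g in genes})
        n_hom = n_oto = 0
        if homology is not None:
            n_genes, n_hom, n_oto = homology_summary(genes, homology, species)
        rows.append(
            {
                "sample": sample,
                "reference": reference,
                "region_size_bp": total_size(list(regions)),
                "genes": n_genes,
                "homologs": n_hom,
                "one_to_one": n_oto,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["sample", "reference", "region_size_bp", "genes", "homologs", "one_to_one"],
    )


# --- annotation I/O ---------------------------------------------------------


def read_genes_bed(path: str | Path) -> list[GeneRecord]:
    """BED6 (gene spans) or BED12 (with exon blocks) annotation."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("track", "#")):
            continue
        f = line.split("\t")
        iv = GenomicInterval(f[0], int(f[1]), int(f[2]))
        gene_id = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}"
        biotype = f[6] if len(f) > 6 and not f[6].isdigit() else "protein_coding"
        exons: tuple[GenomicInterval, ...] = ()
        if len(f) >= 12:  # BED12 blocks
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple(
                GenomicInterval(iv.chrom, iv.start + o, iv.start + o + s)
                for o, s in zip(offsets, sizes)
            )
            biotype = "protein_coding"
        out.append(GeneRecord(gene_id, iv, biotype, exons))
    return out


def read_genes_gff3(path: str | Path) -> list[GeneRecord]:
    """GFF3 annotation via gffutils: gene features with exon children."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    out = []
    for gene in db.features_of_type("gene"):
        gid = gene.attributes.get("ID", [gene.id])[0]
        biotype = gene.attributes.get(
            "biotype", gene.attributes.get("gene_biotype", ["protein_coding"])
        )[0]
        iv = GenomicInterval(gene.seqid, gene.start - 1, gene.end)  # GFF3 is 1-based
        exons = tuple(
            GenomicInterval(e.seqid, e.start - 1, e.end)
            for e in db.children(gene, featuretype="exon", order_by="start")
        )
        out.append(GeneRecord(gid, iv, biotype, exons))
    return out
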