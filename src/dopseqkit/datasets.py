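"""Curated region sets shipped with the package.

These fixtures hold the published B-chromosome region catalogues for the red
fox (samples VVUB2/3/5/6 against the dog CanFam3.1 assembly) and the Chinese
raccoon dog (NPPB1–8, same assembly), their internal deletions, prior BAC
clone mapping evidence, and the worked per-B copy-number examples. They are
the in-package ground truth for the comparative and reporting layers.

The last two raccoon-dog BAC evidence intervals are synthetic 1 bp
stand-ins placed at the published megabase positions (CFA13:34 Mbp,
CFA29:41 Mbp); the exact clone coordinates are not part of the catalogue.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .compare import PresenceMatrix
from .intervals import GenomicInterval, parse_region

#: worked per-B copy-number examples: (extra_copies, n_b, reported per-B)
PER_B_EXAMPLES: tuple[tuple[int, int, int], ...] = ((6, 3, 2), (20, 3, 7))


def _data_path(name: str):
    return resources.files("dopseqkit.data").joinpath(name)


def load_fox_b_matrix() -> PresenceMatrix:
    """Red fox B region catalogue: 14 regions × samples VVUB2/3/5/6 + BAC."""
    with resources.as_file(_data_path("fox_b_regions.tsv")) as p:
        return PresenceMatrix.from_tsv(p)


def load_raccoon_dog_b_matrix() -> PresenceMatrix:
    """Chinese raccoon dog B catalogue: 27 regions × NPPB1–8 + BAC."""
    with resources.as_file(_data_path("raccoon_dog_b_regions.tsv")) as p:
        return PresenceMatrix.from_tsv(p)


def load_fox_b_deletions() -> dict[str, list[GenomicInterval]]:
    """Internal deletions of the fox catalogue, keyed by parent region."""
    with resources.as_file(_data_path("fox_b_deletions.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    out: dict[str, list[GenomicInterval]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["parent_region"], []).append(parse_region(row["deletion"]))
    return out


def load_raccoon_dog_bac_evidence() -> list[GenomicInterval]:
    """Prior BAC mapping evidence for raccoon dog Bs (5 intervals).

    Three are catalogue rows; two are synthetic point stand-ins at the
    published megabase positions of clones not recovered by sequencing.
    """
    with resources.as_file(_data_path("raccoon_dog_bac_evidence.bed")) as p:
        lines = p.read_text().splitlines()
    return [
        GenomicInterval(f[0], int(f[1]), int(f[2]))
        for f in (ln.split("\t") for ln in lines if ln.strip())
    ]


def fox_bac_evidence(matrix: PresenceMatrix | None = None) -> list[GenomicInterval]:
    """The BAC-flagged rows of the fox catalogue as evidence intervals."""
    m = matrix if matrix is not None else load_fox_b_matrix()
    assert m.evidence is not None
    return [parse_region(r) for r, v in m.evidence.items() if v == "+"]
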