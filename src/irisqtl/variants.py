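"""Segregating sites, anchored offsets, and founder allele frequencies.

Takes aligned haplotype sequences for a candidate regulatory region,
polarizes alleles with a designated outgroup, expresses positions as
signed offsets from an anchor column (the alignment column orthologous
to the human OCA2-enhancer SNP rs12913832), and tabulates derived-allele
frequencies among the founders of each group — the computational
content of a variants-by-group summary table for the region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "AlignedHaplotypes",
    "Variant",
    "segregating_sites",
    "anchored_offset",
    "founder_frequency",
    "variant_report",
    "read_alignment",
    "read_sample_metadata",
]

_BASES = {"A", "C", "G", "T"}


@dataclass
class AlignedHaplotypes:
    """Equal-length aligned haplotype sequences with sample metadata.

    Parameters
    ----------
    sequences : mapping haplotype_id -> aligned sequence over
        ``{A, C, G, T, N, -}`` (case-insensitive).
    outgroup_id : haplotype providing ancestral states; it also serves
        as the coordinate reference unless ``reference_id`` is given.
    anchor_column : 0-based alignment column orthologous to the human
        anchor SNP; offsets are reported relative to it.
    groups : mapping haplotype_id -> group label (e.g. species, origin).
    founder : mapping haplotype_id -> bool, True when the haplotype
        belongs to a pedigree founder (frequency denominators use
        founders only, to avoid double-counting transmitted alleles).
    individual : mapping haplotype_id -> individual id; an individual's
        genotype dosage is the count of derived alleles over its
        (typically two) haplotypes.
    """

    sequences: dict
    outgroup_id: str
    anchor_column: int
    groups: dict = field(default_factory=dict)
    founder: dict = field(default_factory=dict)
    individual: dict = field(default_factory=dict)
    reference_id: str | None = None

    def __post_init__(self):
        self.sequences = {k: str(v).upper() for k, v in self.sequences.items()}
        lengths = {len(v) for v in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError("sequences must have equal aligned length")
        (self.length,) = lengths
        if self.outgroup_id not in self.sequences:
            raise ValueError("outgroup sequence missing")
        if not 0 <= self.anchor_column < self.length:
            raise ValueError("anchor column out of bounds")
        bad = set("".join(self.sequences.values())) - (_BASES | {"N", "-"})
        if bad:
            raise ValueError(f"unexpected alignment characters: {sorted(bad)}")
        if self.reference_id is None:
            self.reference_id = self.outgroup_id

    @property
    def ingroup_ids(self):
        return [k for k in self.sequences if k != self.outgroup_id]

    def column(self, c: int) -> dict:
        return {k: v[c] for k, v in self.sequences.items()}


@dataclass
class Variant:
    offset: int
    column: int
    ancestral: str
    derived: str
    polarized: bool
    dosages: dict  # individual -> derived-allele count (np.nan if unknown)
    freq_by_group: dict  # group -> founder derived-allele frequency (np.nan if no founder data)
    haplotype_alleles: dict = field(default_factory=dict, repr=False)

    @property
    def label(self) -> str:
        return f"{self.ancestral} > {self.derived}"


def anchored_offset(column: int, aln: AlignedHaplotypes) -> int:
    """Signed position of an alignment column relative to the anchor.

    Offsets count ungapped bases of the coordinate reference sequence:
    columns where the reference carries a gap do not advance the
    coordinate (and raise if asked for their own offset).  Negative
    offsets are upstream of the anchor, positive downstream.
    """
    if not 0 <= column < aln.length:
        raise ValueError("column out of bounds")
    ref = aln.sequences[aln.reference_id]
    if ref[column] == "-":
        raise ValueError("no reference coordinate: column falls in a reference gap")
    if ref[aln.anchor_column] == "-":
        raise ValueError("anchor column falls in a reference gap")
    # ungapped reference position (1-based) of each column
    upto = lambda c: sum(1 for ch in ref[: c + 1] if ch != "-")
    return upto(column) - upto(aln.anchor_column)


def _group_founder_freq(aln, col_bases, derived, group):
    ids = [
        k
        for k in aln.ingroup_ids
        if aln.groups.get(k) == group and aln.founder.get(k, True)
    ]
    calls = [col_bases[k] for k in ids if col_bases[k] in _BASES]
    if not calls:
        return np.nan
    return sum(1 for b in calls if b == derived) / len(calls)


def segregating_sites(aln: AlignedHaplotypes) -> list[Variant]:
    """Biallelic segregating sites among ingroup haplotypes.

    A column qualifies when ingroup haplotypes carry exactly two
    distinct bases (gaps and N ignored).  The ancestral state is the
    outgroup base when it matches one of the two alleles; otherwise the
    site is flagged unpolarized and the minor allele is reported as
    derived.  Columns with more than two alleles are excluded with a
    warning; columns where the coordinate reference is gapped are
    excluded (they have no anchored position).
    """
    out = []
    ref = aln.sequences[aln.reference_id]
    outg = aln.sequences[aln.outgroup_id]
    groups = sorted({g for k, g in aln.groups.items() if k != aln.outgroup_id})
    for c in range(aln.length):
        ingroup = {k: aln.sequences[k][c] for k in aln.ingroup_ids}
        alleles = sorted({b for b in ingroup.values() if b in _BASES})
        if len(alleles) < 2:
            continue
        if len(alleles) > 2:
            warnings.warn(f"column {c}: >2 alleles, site excluded")
            continue
        if ref[c] == "-":
            continue  # no anchored coordinate for this column
        anc_base = outg[c]
        if anc_base in alleles:
            ancestral, polarized = anc_base, True
            derived = alleles[0] if alleles[1] == ancestral else alleles[1]
        else:
            polarized = False
            counts = {a: sum(1 for b in ingroup.values() if b == a) for a in alleles}
            ancestral = max(alleles, key=lambda a: (counts[a], a))  # major allele
            derived = alleles[0] if alleles[1] == ancestral else alleles[1]

        dosages = {}
        if aln.individual:
            by_ind = {}
            for hid, base in ingroup.items():
                ind = aln.individual.get(hid)
                if ind is not None:
                    by_ind.setdefault(ind, []).append(base)
            for ind, bases in by_ind.items():
                called = [b for b in bases if b in _BASES]
                dosages[ind] = sum(1 for b in called if b == derived) if called else np.nan

        freq = {g: _group_founder_freq(aln, ingroup, derived, g) for g in groups}
        out.append(
            Variant(
                offset=anchored_offset(c, aln),
                column=c,
                ancestral=ancestral,
                derived=derived,
                polarized=polarized,
                dosages=dosages,
                freq_by_group=freq,
                haplotype_alleles=ingroup,
            )
        )
    return out


def founder_frequency(v: Variant, group: str) -> float:
    """Derived-allele frequency among founder haplotypes of a group."""
    if group not in v.freq_by_group:
        raise KeyError(f"group {group!r} not tabulated for this variant")
    return v.freq_by_group[group]


def variant_report(
    aln: AlignedHaplotypes,
    assoc: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Variants-by-group summary table for the candidate region.

    One row per segregating site: anchored offset, ``ancestral >
    derived`` notation, founder derived-allele frequency per group
    (NA where a group has no sequenced founders), polarization flag,
    plus association p-values merged in when an ``assoc`` table (from
    the mixed-model scan, keyed by offset in its ``variant`` column)
    is supplied.
    """
    variants = segregating_sites(aln)
    groups = sorted({g for k, g in aln.groups.items() if k != aln.outgroup_id})
    cols = ["offset", "variant", "polarized"] + [f"freq_{g}" for g in groups]
    rows = []
    for v in sorted(variants, key=lambda v: v.offset):
        row = {"offset": v.offset, "variant": v.label, "polarized": v.polarized}
        for g in groups:
            row[f"freq_{g}"] = v.freq_by_group.get(g, np.nan)
        rows.append(row)
    table = pd.DataFrame(rows, columns=cols)
    if assoc is not None and not table.empty:
        merged = assoc.rename(columns={"variant": "offset"}).copy()
        merged["offset"] = merged["offset"].astype(int)
        table = table.merge(merged[["offset", "p"]], on="offset", how="left")
    return table


# ---------------------------------------------------------------------------
# I/O


def read_alignment(
    fasta_path,
    outgroup_id: str,
    anchor_column: int,
    metadata: pd.DataFrame | None = None,
    reference_id: str | None = None,
) -> AlignedHaplotypes:
    """Read an aligned FASTA plus an optional sample-metadata table.

    The metadata TSV has columns ``id group founder_flag individual``
    (one row per haplotype).
    """
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    groups, founder, individual = {}, {}, {}
    if metadata is not None:
        for _, r in metadata.iterrows():
            hid = str(r["id"])
            groups[hid] = str(r["group"])
            founder[hid] = bool(int(r["founder_flag"]))
            individual[hid] = str(r["individual"])
    return AlignedHaplotypes(
        sequences=seqs,
        outgroup_id=outgroup_id,
        anchor_column=anchor_column,
        groups=groups,
        founder=founder,
        individual=individual,
        reference_id=reference_id,
    )


def read_sample_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_variant_tsv(variants: list[Variant], path) -> None:
    """Minimal VCF-like TSV: offset, ancestral, derived, per-individual dosage."""
    inds = sorted({i for v in variants for i in v.dosages})
    rows = []
    for v in sorted(variants, key=lambda v: v.offset):
        row = {"offset": v.offset, "ancestral": v.ancestral, "derived": v.derived}
        for i in inds:
            row[i] = v.dosages.get(i, np.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="NA")
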