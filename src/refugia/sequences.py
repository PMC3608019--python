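"""Aligned mitochondrial sequences: IO, haplotype collapsing, p-distances.

An :class:`Alignment` joins each sequence to its individual, population and
species labels.  Identical sequences (compared literally, including ``N``
and gaps) collapse to haplotypes; distances are mismatch counts or
proportions with pairwise deletion of sites where either sequence is
ambiguous (``N``) or gapped.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 5}
_VALID = 4  # codes < 4 are resolved bases

__all__ = [
    "Alignment",
    "HaplotypeSet",
    "read_alignment",
    "write_fasta",
    "collapse_haplotypes",
    "pairwise_differences",
    "distance_matrix",
]


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE[ch] for ch in seq.upper()], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"invalid character {exc.args[0]!r} in sequence") from exc


@dataclass
class Alignment:
    """Equal-length sequences with individual → population → species metadata."""

    individuals: list[str]
    populations: list[str]
    species: list[str]
    sequences: list[str]
    _matrix: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            ref = len(self.sequences[0])
            for ind, s in zip(self.individuals, self.sequences):
                if len(s) != ref:
                    raise ValueError(
                        f"sequence for {ind!r} has length {len(s)}, expected {ref}"
                    )
        if len(set(self.individuals)) != len(self.individuals):
            dupes = pd.Series(self.individuals)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValueError(f"duplicate individual ids: {dupes}")

    def __len__(self) -> int:
        return len(self.individuals)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def matrix(self) -> np.ndarray:
        """(n_individuals, n_sites) uint8 encoding; computed once."""
        if self._matrix is None:
            self._matrix = np.vstack([encode(s) for s in self.sequences])
        return self._matrix

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual": self.individuals,
                "population": self.populations,
                "species": self.species,
                "sequence": self.sequences,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Alignment":
        return cls(
            individuals=list(df["individual"]),
            populations=list(df["population"]),
            species=list(df["species"]),
            sequences=list(df["sequence"]),
        )

    def subset(self, keep: set[str]) -> "Alignment":
        idx = [i for i, ind in enumerate(self.individuals) if ind in keep]
        return Alignment(
            individuals=[self.individuals[i] for i in idx],
            populations=[self.populations[i] for i in idx],
            species=[self.species[i] for i in idx],
            sequences=[self.sequences[i] for i in idx],
        )


@dataclass
class HaplotypeSet:
    """Distinct sequences, their carriers, and (once assigned) mitochondrial lineages."""

    haplotype_ids: list[str]
    sequences: list[str]
    members: dict[str, list[str]]  # haplotype id -> individual ids
    lineages: dict[str, str] = field(default_factory=dict)  # haplotype id -> lineage label

    def haplotype_of(self) -> dict[str, str]:
        """individual id -> haplotype id."""
        return {ind: h for h, inds in self.members.items() for ind in inds}


def read_alignment(fasta_path: str | Path, populations_path: str | Path) -> Alignment:
    """Join a FASTA (headers = individual ids, or ``ind|pop|species``) to a population CSV.

    The CSV needs columns ``individual, population, species`` (lon/lat extra
    columns are ignored here and consumed by the landscape stage).
    """
    meta = pd.read_csv(populations_path).set_index("individual")
    individuals, populations, species, sequences = [], [], [], []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        ind = rec.id.split("|")[0]
        if ind not in meta.index:
            raise ValueError(f"individual {ind!r} missing from population table")
        individuals.append(ind)
        populations.append(str(meta.loc[ind, "population"]))
        species.append(str(meta.loc[ind, "species"]))
        sequences.append(str(rec.seq).upper())
    if not individuals:
        raise ValueError(f"no records in {fasta_path}")
    return Alignment(individuals, populations, species, sequences)


def write_fasta(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for ind, pop, sp, seq in zip(aln.individuals, aln.populations, aln.species, aln.sequences):
            fh.write(f">{ind}|{pop}|{sp}\n{seq}\n")


def collapse_haplotypes(aln: Alignment) -> HaplotypeSet:
    """Merge literally identical sequences into haplotypes (first-seen order)."""
    if len(aln) == 0:
        raise ValueError("empty alignment")
    seq_to_hap: dict[str, str] = {}
    ids: list[str] = []
    seqs: list[str] = []
    members: dict[str, list[str]] = {}
    for ind, seq in zip(aln.individuals, aln.sequences):
        h = seq_to_hap.get(seq)
        if h is None:
            h = f"H{len(ids) + 1:03d}"
            seq_to_hap[seq] = h
            ids.append(h)
            seqs.append(seq)
            members[h] = []
        members[h].append(ind)
    return HaplotypeSet(haplotype_ids=ids, sequences=seqs, members=members)


def pairwise_differences(a: str | np.ndarray, b: str | np.ndarray) -> tuple[int, int, float]:
    """Mismatch count, compared sites and mismatch proportion for two sequences.

    Sites where either sequence is ``N`` or ``-`` are excluded (pairwise
    deletion).  Raises if no site remains comparable.
    """
    ea = encode(a) if isinstance(a, str) else a
    eb = encode(b) if isinstance(b, str) else b
    if ea.shape != eb.shape:
        raise ValueError("sequences differ in length")
    valid = (ea < _VALID) & (eb < _VALID)
    compared = int(valid.sum())
    if compared == 0:
        raise ValueError("no comparable sites (all ambiguous or gapped)")
    mismatches = int(((ea != eb) & valid).sum())
    return mismatches, compared, mismatches / compared


def distance_matrix(
    sequences: list[str], labels: list[str] | None = None, kind: str = "proportion"
) -> tuple[np.ndarray, list[str]]:
    """Symmetric pairwise distance matrix (``proportion`` p-distance or mismatch ``count``)."""
    if kind not in ("proportion", "count"):
        raise ValueError("kind must be 'proportion' or 'count'")
    labels = labels if labels is not None else [f"S{i}" for i in range(len(sequences))]
    enc = [encode(s) for s in sequences]
    n = len(enc)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            cnt, _, prop = pairwise_differences(enc[i], enc[j])
            d[i, j] = d[j, i] = prop if kind == "proportion" else cnt
    return d, labels
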