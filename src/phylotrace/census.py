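"""Census matrices of fold-superfamily (FSF) abundance and their encoding.

A census matrix records, for every sampled proteome (taxon), how many times
each SCOP fold superfamily occurs.  Two summaries recur throughout the
pipeline: FSF *use* (occurrence: the number of distinct FSFs with nonzero
abundance, the "vocabulary") and FSF *reuse* (total abundance, the "database
size").  Phylogenetic matrices are built from the *universal* subset of FSFs
-- those present in at least one member of every supergroup (Archaea,
Bacteria, Eukarya, Viruses) -- and abundances are log-rescaled per character
to an ordered alphanumeric scale of 24 (or 32 or 64) states suitable for
Wagner parsimony.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CensusMatrix",
    "CharacterMatrix",
    "read_census",
    "write_census",
    "read_group_map",
    "universal_fsf_ids",
    "filter_universal",
    "use_reuse",
    "encode",
    "to_nexus",
]

SUPERGROUPS = ("A", "B", "E", "V")

# 24 states map to "0-9 and A-N"; the 64-state alphabet additionally needs
# lowercase letters plus two extra glyphs beyond the 62 alphanumerics.
_ALPHABET = string.digits + string.ascii_uppercase + string.ascii_lowercase + "!@"
VALID_STATE_COUNTS = (24, 32, 64)


@dataclass
class CensusMatrix:
    """Taxa x FSF integer abundance table with supergroup labels."""

    taxa: list[str]
    groups: dict[str, str]
    fsf_ids: list[str]
    abundance: np.ndarray  # shape (n_taxa, n_fsf), non-negative ints

    def __post_init__(self) -> None:
        self.abundance = np.asarray(self.abundance)
        if self.abundance.shape != (len(self.taxa), len(self.fsf_ids)):
            raise ValueError(
                f"abundance shape {self.abundance.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.fsf_ids)} FSFs"
            )
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon ids")
        if len(set(self.fsf_ids)) != len(self.fsf_ids):
            raise ValueError("duplicate FSF ids")
        if not np.issubdtype(self.abundance.dtype, np.integer):
            if not np.all(self.abundance == np.floor(self.abundance)):
                raise ValueError("abundances must be integers")
            self.abundance = self.abundance.astype(np.int64)
        if (self.abundance < 0).any():
            i, j = np.argwhere(self.abundance < 0)[0]
            raise ValueError(
                f"negative abundance for taxon {self.taxa[i]!r}, FSF {self.fsf_ids[j]!r}"
            )
        missing = [t for t in self.taxa if t not in self.groups]
        if missing:
            raise ValueError(f"taxa missing a supergroup label: {missing}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.abundance.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.abundance, index=self.taxa, columns=self.fsf_ids)

    def subset_taxa(self, taxa: Sequence[str]) -> "CensusMatrix":
        missing = [t for t in taxa if t not in self.taxa]
        if missing:
            raise KeyError(f"unknown taxa: {missing}")
        idx = [self.taxa.index(t) for t in taxa]
        return CensusMatrix(
            taxa=list(taxa),
            groups={t: self.groups[t] for t in taxa},
            fsf_ids=list(self.fsf_ids),
            abundance=self.abundance[idx, :].copy(),
        )


@dataclass
class CharacterMatrix:
    """Ordered multistate matrix derived from a census, ready for parsimony."""

    taxa: list[str]
    characters: list[str]
    states: np.ndarray  # (n_taxa, n_chars) ints in [0, n_states-1]
    n_states: int
    parsimony_informative: np.ndarray = field(default=None)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.n_states not in VALID_STATE_COUNTS:
            raise ValueError(f"n_states must be one of {VALID_STATE_COUNTS}")
        if self.states.shape != (len(self.taxa), len(self.characters)):
            raise ValueError("states shape does not match taxa x characters")
        if self.states.size and (
            self.states.min() < 0 or self.states.max() > self.n_states - 1
        ):
            raise ValueError(f"states must lie in [0, {self.n_states - 1}]")
        if self.parsimony_informative is None:
            self.parsimony_informative = _informative_flags(self.states)

    @property
    def symbols(self) -> str:
        return _ALPHABET[: self.n_states]

    def states_for(self, taxa_order: Sequence[str]) -> np.ndarray:
        idx = [self.taxa.index(t) for t in taxa_order]
        return self.states[idx, :]

    def subset_taxa(self, taxa: Sequence[str]) -> "CharacterMatrix":
        return CharacterMatrix(
            taxa=list(taxa),
            characters=list(self.characters),
            states=self.states_for(taxa),
            n_states=self.n_states,
            provenance=dict(self.provenance),
        )

    def resample_characters(self, rng: np.random.Generator) -> "CharacterMatrix":
        """Bootstrap replicate: characters drawn with replacement."""
        cols = rng.integers(0, len(self.characters), size=len(self.characters))
        return CharacterMatrix(
            taxa=list(self.taxa),
            characters=[f"{self.characters[c]}#{i}" for i, c in enumerate(cols)],
            states=self.states[:, cols],
            n_states=self.n_states,
            provenance={**self.provenance, "bootstrap": True},
        )


def _informative_flags(states: np.ndarray) -> np.ndarray:
    flags = np.zeros(states.shape[1], dtype=bool)
    for j in range(states.shape[1]):
        _, counts = np.unique(states[:, j], return_counts=True)
        flags[j] = (counts >= 2).sum() >= 2
    return flags


# -- I/O -------------------------------------------------------------------


def read_group_map(path) -> dict[str, str]:
    """Two-column TSV (taxon, supergroup label) without header."""
    df = pd.read_csv(path, sep="\t", header=None, names=["taxon", "group"], dtype=str)
    if df["taxon"].duplicated().any():
        dupes = df.loc[df["taxon"].duplicated(), "taxon"].tolist()
        raise ValueError(f"duplicate taxa in group map: {dupes}")
    return dict(zip(df["taxon"], df["group"]))


def read_census(path, group_map: Mapping[str, str]) -> CensusMatrix:
    """Read a tab-separated census (header = FSF ids, first column = taxon)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicate FSF column ids in census file: {dupes}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    fsf_ids = [str(c) for c in df.columns]
    taxa = [str(t) for t in df.index]
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxon row ids in census file")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = df.columns[
            [not np.issubdtype(df[c].dtype, np.number) for c in df.columns]
        ]
        raise ValueError(f"non-numeric abundance column(s): {list(bad)}")
    if np.isnan(values.astype(float)).any():
        i, j = np.argwhere(np.isnan(values.astype(float)))[0]
        raise ValueError(f"missing value at taxon {taxa[i]!r}, FSF {fsf_ids[j]!r}")
    if not np.all(values == np.floor(values)):
        i, j = np.argwhere(values != np.floor(values))[0]
        raise ValueError(
            f"non-integer abundance at taxon {taxa[i]!r}, FSF {fsf_ids[j]!r}"
        )
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(f"negative abundance at taxon {taxa[i]!r}, FSF {fsf_ids[j]!r}")
    missing = [t for t in taxa if t not in group_map]
    if missing:
        raise ValueError(f"taxa missing from group map: {missing}")
    return CensusMatrix(
        taxa=taxa,
        groups={t: group_map[t] for t in taxa},
        fsf_ids=fsf_ids,
        abundance=values.astype(np.int64),
    )


def write_census(census: CensusMatrix, path) -> None:
    census.to_frame().to_csv(path, sep="\t", index_label="taxon")


# -- filtering and summaries ----------------------------------------------


def universal_fsf_ids(
    census: CensusMatrix, required_groups: Optional[Iterable[str]] = None
) -> list[str]:
    """FSFs with nonzero abundance in at least one taxon of every group."""
    if required_groups is None:
        required_groups = sorted(set(census.groups.values()))
    required_groups = list(required_groups)
    present_groups = set(census.groups.values())
    unknown = [g for g in required_groups if g not in present_groups]
    if unknown:
        raise ValueError(f"required groups absent from census: {unknown}")
    nonzero = census.abundance > 0
    keep = np.ones(len(census.fsf_ids), dtype=bool)
    keep &= nonzero.any(axis=0)  # drop all-zero columns regardless
    for g in required_groups:
        rows = [i for i, t in enumerate(census.taxa) if census.groups[t] == g]
        keep &= nonzero[rows, :].any(axis=0)
    return [f for f, k in zip(census.fsf_ids, keep) if k]


def filter_universal(
    census: CensusMatrix, required_groups: Optional[Iterable[str]] = None
) -> CensusMatrix:
    """Retain only universal (e.g., ABEV) FSFs; taxa are unchanged."""
    keep = universal_fsf_ids(census, required_groups)
    if not keep:
        raise ValueError(
            "no FSF is present in every required group; broaden taxon sampling "
            "or relax the required groups"
        )
    idx = [census.fsf_ids.index(f) for f in keep]
    return CensusMatrix(
        taxa=list(census.taxa),
        groups=dict(census.groups),
        fsf_ids=keep,
        abundance=census.abundance[:, idx].copy(),
    )


def use_reuse(
    census: CensusMatrix, fsf_subset: Optional[Iterable[str]] = None
) -> pd.DataFrame:
    """Per-taxon FSF use (occurrence) and reuse (abundance) over a subset."""
    if fsf_subset is None:
        cols = np.arange(len(census.fsf_ids))
    else:
        fsf_subset = list(fsf_subset)
        unknown = [f for f in fsf_subset if f not in census.fsf_ids]
        if unknown:
            raise KeyError(f"FSFs not in census: {unknown}")
        pos = {f: i for i, f in enumerate(census.fsf_ids)}
        cols = np.array([pos[f] for f in fsf_subset], dtype=int)
    sub = census.abundance[:, cols] if len(cols) else np.zeros((len(census.taxa), 0), int)
    return pd.DataFrame(
        {
            "taxon": census.taxa,
            "group": [census.groups[t] for t in census.taxa],
            "use": (sub > 0).sum(axis=1),
            "reuse": sub.sum(axis=1),
        }
    )


# -- encoding --------------------------------------------------------------


def encode(census: CensusMatrix, n_states: int = 24) -> CharacterMatrix:
    """Log-rescale abundances per character to an ordered 0..S-1 scale.

    For character j with maximum abundance m_j > 0,
    ``s_ij = round((S-1) * ln(a_ij + 1) / ln(m_j + 1))`` with half-away-from-
    zero rounding.  All-zero characters are dropped.  The map is monotone in
    abundance within each character.
    """
    if n_states not in VALID_STATE_COUNTS:
        raise ValueError(f"n_states must be one of {VALID_STATE_COUNTS}")
    if not census.taxa or not census.fsf_ids:
        raise ValueError("census is empty")
    a = census.abundance.astype(float)
    maxima = a.max(axis=0)
    keep = maxima > 0
    a = a[:, keep]
    maxima = maxima[keep]
    characters = [f for f, k in zip(census.fsf_ids, keep) if k]
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = (n_states - 1) * np.log1p(a) / np.log1p(maxima)[None, :]
    # constant nonzero columns have a_ij == m_j everywhere -> state S-1
    states = np.floor(scaled + 0.5).astype(np.int64)
    return CharacterMatrix(
        taxa=list(census.taxa),
        characters=characters,
        states=states,
        n_states=n_states,
        provenance={
            "encoding": "per-character log normalization",
            "n_states": n_states,
            "dropped_all_zero": int((~keep).sum()),
        },
    )


def to_nexus(matrix: CharacterMatrix, path) -> None:
    """Write a NEXUS DATA block with an ordered-characters assumption."""
    symbols = matrix.symbols
    lines = [
        "#NEXUS",
        "",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={len(matrix.taxa)} NCHAR={len(matrix.characters)};",
        f'    FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=? GAP=-;',
        "    MATRIX",
    ]
    width = max(len(t) for t in matrix.taxa) + 2
    for i, taxon in enumerate(matrix.taxa):
        row = "".join(symbols[s] for s in matrix.states[i])
        safe = taxon.replace(" ", "_")
        lines.append(f"    {safe:<{width}}{row}")
    lines += [
        "    ;",
        "END;",
        "",
        "BEGIN ASSUMPTIONS;",
        "    TYPESET * default = ord: 1-" + str(len(matrix.characters)) + ";",
        "END;",
        "",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def from_nexus(path, n_states: int) -> CharacterMatrix:
    """Parse a NEXUS standard matrix back (round-trip counterpart of to_nexus)."""
    import dendropy

    data = dendropy.StandardCharacterMatrix.get(path=path, schema="nexus")
    taxa = [t.label.replace(" ", "_") for t in data.taxon_namespace]
    symbols = _ALPHABET[:n_states]
    rows = []
    for taxon in data.taxon_namespace:
        seq = data[taxon]
        rows.append([symbols.index(str(ch)) for ch in seq.symbols_as_list()])
    states = np.array(rows, dtype=np.int64)
    return CharacterMatrix(
        taxa=taxa,
        characters=[f"c{j}" for j in range(states.shape[1])],
        states=states,
        n_states=n_states,
    )
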