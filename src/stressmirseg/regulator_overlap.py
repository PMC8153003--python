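"""Set-overlap analysis of shared miRNA regulators (TFs and lncRNA decoys).

Each miRNA carries a set of upstream regulators — transcription factors
with ChIP evidence of binding its promoter, or lncRNAs predicted to bind
and sequester (decoy) it. This module computes the pairwise comparison
matrix of shared regulators across miRNAs and the set common to all of
them.

Packaged fixtures transcribe the published shared-regulator lists for the
four study miRNAs; since only the shared elements are public, each
miRNA's fixture set is the union of its printed pairwise intersections
plus clearly namespaced ``DECOY_*`` padding unique to that miRNA, which
reproduces every printed intersection exactly while keeping the
operations non-trivial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from pathlib import Path
from typing import Mapping

import pandas as pd


class OverlapError(ValueError):
    """Invalid regulator-set input."""


@dataclass(frozen=True)
class RegulatorSets:
    """Mapping miRNA -> set of regulator identifiers."""

    sets: Mapping[str, frozenset[str]]
    provenance: str = ""

    def __post_init__(self):
        for mirna, regs in self.sets.items():
            if not mirna or not isinstance(mirna, str):
                raise OverlapError(f"invalid miRNA key {mirna!r}")
            for r in regs:
                if not r or not isinstance(r, str) or r != r.strip():
                    raise OverlapError(
                        f"invalid regulator identifier {r!r} for {mirna}"
                    )

    def __getitem__(self, mirna: str) -> frozenset[str]:
        try:
            return self.sets[mirna]
        except KeyError:
            raise OverlapError(
                f"unknown miRNA {mirna!r}; known: {sorted(self.sets)}"
            ) from None

    @property
    def mirnas(self) -> tuple[str, ...]:
        return tuple(self.sets)


@dataclass(frozen=True)
class OverlapMatrix:
    mirnas: tuple[str, ...]
    #: unordered pair -> sorted tuple of shared regulators
    pairs: Mapping[frozenset, tuple[str, ...]]
    common_all: tuple[str, ...]

    def overlap(self, a: str, b: str) -> tuple[str, ...]:
        key = frozenset((a, b))
        if key not in self.pairs:
            raise OverlapError(f"unknown miRNA pair ({a!r}, {b!r})")
        return self.pairs[key]

    def to_frame(self) -> pd.DataFrame:
        """Lower-triangle comparison matrix of comma-joined shared lists."""
        out = pd.DataFrame("", index=self.mirnas[1:], columns=self.mirnas[:-1])
        for i, j in combinations(range(len(self.mirnas)), 2):
            a, b = self.mirnas[i], self.mirnas[j]
            out.loc[b, a] = ", ".join(self.overlap(a, b))
        return out


def pairwise_overlap(sets: RegulatorSets) -> OverlapMatrix:
    """Exact set intersection for every unordered miRNA pair, plus the
    regulators common to all miRNAs. Output is deterministically sorted."""
    mirnas = sets.mirnas
    if len(mirnas) < 2:
        raise OverlapError("need at least 2 miRNA sets")
    pairs = {}
    for a, b in combinations(mirnas, 2):
        pairs[frozenset((a, b))] = tuple(sorted(sets[a] & sets[b]))
    return OverlapMatrix(mirnas, pairs, common_to_all(sets))


def common_to_all(sets: RegulatorSets) -> tuple[str, ...]:
    """Regulators shared by every miRNA in the collection."""
    mirnas = sets.mirnas
    if len(mirnas) < 2:
        raise OverlapError("need at least 2 miRNA sets")
    common = set(sets[mirnas[0]])
    for m in mirnas[1:]:
        common &= sets[m]
    return tuple(sorted(common))


def load_regulator_sets(path: str | Path, provenance: str = "") -> RegulatorSets:
    """Read a two-column TSV (miRNA, regulator), whitespace-trimmed,
    case-sensitive."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if list(frame.columns[:2]) != ["miRNA", "regulator"]:
        raise OverlapError(
            f"{path}: expected columns 'miRNA', 'regulator', got "
            f"{list(frame.columns)}"
        )
    sets: dict[str, set[str]] = {}
    for row in frame.itertuples(index=False):
        sets.setdefault(str(row.miRNA).strip(), set()).add(
            str(row.regulator).strip()
        )
    return RegulatorSets({k: frozenset(v) for k, v in sets.items()}, provenance)


def _packaged(name: str) -> Path:
    return Path(str(resources.files("stressmirseg").joinpath("data", name)))


def load_tf_sets() -> RegulatorSets:
    """Packaged ChIP-derived TF regulator sets for the four study miRNAs."""
    return load_regulator_sets(_packaged("tf_sets.tsv"), "ChIP-derived TF")


def load_lncrna_sets() -> RegulatorSets:
    """Packaged predicted lncRNA decoy sets for the four study miRNAs."""
    return load_regulator_sets(_packaged("lncrna_sets.tsv"), "predicted lncRNA")
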