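"""Desk-scale synthetic stand-ins for the two training datasets: a
fragment-grammar SMILES corpus (valid by construction, small vocabulary)
and an activity table whose labels are driven by a planted substructure
motif plus independent label noise.

The grammar concatenates linearly-attachable fragments, each of which keeps
every atom within valence when extended on either side, so any sequence of
fragments is a parseable molecule.  The default motif is a furan ring,
giving the toy task the same enriched-substructure bias structure as a
real substructure-driven activity cliff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from smilesrl.qsar import ActivityRecord

# Fragments safe under plain concatenation (linear attachment on both ends).
DEFAULT_FRAGMENTS = (
    "C", "CC", "CCC", "N", "O", "C(C)", "C(=O)",
    "c1ccccc1", "C1CCCCC1",
)

DEFAULT_MOTIF = "c1ccoc1"  # furan, planted as an in-chain unit


@dataclass
class FixtureConfig:
    n_molecules: int = 1000
    seed: int = 0
    fragment_set: tuple[str, ...] = DEFAULT_FRAGMENTS
    motif: str = DEFAULT_MOTIF
    motif_prevalence: float = 0.3
    label_noise: float = 0.05
    min_units: int = 2
    max_units: int = 4

    def __post_init__(self) -> None:
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")
        if not 0.0 < self.motif_prevalence < 1.0:
            raise ValueError("motif_prevalence must be in (0, 1)")
        for frag in self.fragment_set:
            if Chem.MolFromSmiles(frag) is None:
                raise ValueError(f"fragment {frag!r} is not valid SMILES")


def _assemble(rng: np.random.Generator, config: FixtureConfig,
              with_motif: bool) -> str:
    n_units = int(rng.integers(config.min_units, config.max_units + 1))
    units = [config.fragment_set[int(i)]
             for i in rng.integers(0, len(config.fragment_set), n_units)]
    if with_motif:
        pos = int(rng.integers(0, n_units + 1))
        units.insert(pos, config.motif)
    return "".join(units)


def has_motif(smiles: str, motif: str = DEFAULT_MOTIF) -> bool:
    mol = Chem.MolFromSmiles(smiles)
    patt = Chem.MolFromSmarts(motif)
    return mol is not None and mol.HasSubstructMatch(patt)


def generate_corpus(config: FixtureConfig) -> list[str]:
    """Seeded corpus of valid SMILES; a Bernoulli(motif_prevalence) draw
    decides per molecule whether the motif unit is planted."""
    if config.n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = np.random.default_rng(config.seed)
    corpus = []
    for _ in range(config.n_molecules):
        with_motif = rng.random() < config.motif_prevalence
        corpus.append(_assemble(rng, config, with_motif))
    return corpus


def generate_activity_set(config: FixtureConfig,
                          corpus: list[str] | None = None
                          ) -> list[ActivityRecord]:
    """Activity records over a corpus: label 1 iff the motif is present,
    then flipped with probability ``label_noise``; pChEMBL values are
    synthesized on the matching side of the 6.5 cut (7.5 +/- 0.5 for
    actives, 5.5 +/- 0.5 for inactives) so curation reproduces the labels.
    """
    if corpus is None:
        corpus = generate_corpus(config)
    rng = np.random.default_rng(config.seed + 104729)  # offset label stream
    records = []
    for smiles in corpus:
        label = int(has_motif(smiles, config.motif))
        if rng.random() < config.label_noise:
            label = 1 - label
        base = 7.5 if label else 5.5
        pchembl = base + float(rng.uniform(-0.5, 0.5))
        records.append(ActivityRecord(smiles=smiles, pchembl=pchembl))
    return records


def write_corpus(path: str, corpus: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(corpus) + "\n")


def read_corpus(path: str) -> list[str]:
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip()]


def write_activity_csv(path: str, records: list[ActivityRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("smiles,pchembl,annotation\n")
        for rec in records:
            p = "" if rec.pchembl is None else f"{rec.pchembl:.4f}"
            a = rec.annotation or ""
            fh.write(f"{rec.smiles},{p},{a}\n")


def read_activity_csv(path: str) -> list[ActivityRecord]:
    import csv

    records = []
    with open(path) as fh:
        for row in csv.DictReader(fh):
            pchembl = float(row["pchembl"]) if row.get("pchembl") else None
            annotation = row.get("annotation") or None
            records.append(ActivityRecord(smiles=row["smiles"],
                                          pchembl=pchembl,
                                          annotation=annotation))
    return records
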