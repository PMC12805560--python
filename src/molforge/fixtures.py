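"""Synthetic SMILES batch generator for tests and capacity checks.

Produces deterministic batches of chemically trivial molecules (no
stereocenters, no charges) so that large-batch runs exercise pipeline
robustness rather than embedder corner cases.  Families:

``alkanes``
    Linear alkanes, chain lengths cycling 1..12.
``alcohols``
    Linear primary alcohols, chain lengths cycling 1..10.
``mixed``
    Seeded random draws from a pool of small alkanes, alcohols, ethers,
    carbonyls and rings (the default for capacity tests).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .chem import BatchInput
from .errors import BadParam

FAMILIES = ("alkanes", "alcohols", "mixed")

_MIXED_POOL = (
    "C", "CC", "CCC", "CCCC", "CCCCC", "CCCCCC", "CC(C)C", "CC(C)CC",
    "CO", "CCO", "CCCO", "CC(O)C", "OCCO",
    "COC", "CCOC", "CCOCC",
    "C=C", "CC=C", "C#C", "C=O", "CC=O", "CC(=O)C", "CC(=O)O", "OC=O",
    "C1CC1", "C1CCC1", "C1CCCC1", "C1CCCCC1", "c1ccccc1",
    "CN", "CCN", "NC(=O)N",
)


@dataclass(frozen=True)
class FixtureSpec:
    count: int
    family: str = "mixed"
    seed: int = 0

    def __post_init__(self):
        if self.count < 1:
            raise BadParam(f"fixture count must be >= 1, got {self.count}")
        if self.family not in FAMILIES:
            raise BadParam(f"unknown family {self.family!r}; expected one of {FAMILIES}")


def alkane_smiles(n: int) -> str:
    """Linear alkane with ``n`` carbons: ``"C" * n``."""
    if n < 1:
        raise BadParam(f"alkane length must be >= 1, got {n}")
    return "C" * n


def batch_fixture(spec: FixtureSpec) -> BatchInput:
    """A deterministic batch of valid SMILES for the given spec."""
    if spec.family == "alkanes":
        entries = [alkane_smiles(i % 12 + 1) for i in range(spec.count)]
    elif spec.family == "alcohols":
        entries = ["C" * (i % 10 + 1) + "O" for i in range(spec.count)]
    else:
        rng = np.random.RandomState(spec.seed)
        idx = rng.randint(0, len(_MIXED_POOL), size=spec.count)
        entries = [_MIXED_POOL[i] for i in idx]
    return BatchInput(entries=tuple(entries), source="inline")


def write_fixture_csv(spec: FixtureSpec, path: str | Path) -> Path:
    """Write a fixture batch as a one-column CSV consumable by ``--csv``."""
    path = Path(path)
    batch = batch_fixture(spec)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        for smiles in batch:
            writer.writerow([smiles])
    return path
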