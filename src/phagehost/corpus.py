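"""Corpus assembly: host-genus selection and seeded train/test splitting."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io_formats import HostLabelTable


@dataclass
class CorpusSplit:
    train_ids: list[str]
    test_ids: list[str]
    seed: int
    fraction: float

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")


def select_top_genera(labels: HostLabelTable, n: int) -> set[str]:
    """Return the n genera with the most phages; ties break alphabetically."""
    if n < 1:
        raise ValueError("n must be >= 1")
    counts = labels.genus_counts()
    if n > len(counts):
        warnings.warn(
            f"requested top {n} genera but only {len(counts)} are present; keeping all",
            stacklevel=2,
        )
        return set(counts)
    ranked = sorted(counts, key=lambda g: (-counts[g], g))
    return set(ranked[:n])


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_corpus(
    phage_ids: Iterable[str],
    fraction: float = 0.8,
    seed: int = 0,
    labels: HostLabelTable | None = None,
    stratify_by_genus: bool = False,
) -> CorpusSplit:
    """Randomly split phage ids into train/test partitions.

    Deterministic for a fixed seed.  |train| = round(fraction * total).
    With stratification, each genus contributes round(fraction * n_genus)
    phages to the training set (multi-genus phages are allocated under
    their alphabetically first genus).
    """
    ids = sorted(set(phage_ids))
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if len(ids) < 2:
        raise ValueError("need at least 2 phages to split")
    rng = np.random.default_rng(seed)

    if stratify_by_genus:
        if labels is None:
            raise ValueError("stratified split requires a host label table")
        groups: dict[str, list[str]] = {}
        for pid in ids:
            genera = sorted(labels.genera_of(pid))
            key = genera[0] if genera else ""
            groups.setdefault(key, []).append(pid)
        train: list[str] = []
        test: list[str] = []
        for key in sorted(groups):
            members = groups[key]
            perm = rng.permutation(len(members))
            n_train = _round_half_up(fraction * len(members))
            shuffled = [members[i] for i in perm]
            train.extend(shuffled[:n_train])
            test.extend(shuffled[n_train:])
    else:
        perm = rng.permutation(len(ids))
        n_train = _round_half_up(fraction * len(ids))
        shuffled = [ids[i] for i in perm]
        train, test = shuffled[:n_train], shuffled[n_train:]

    if not train or not test:
        raise ValueError(
            f"fraction {fraction} yields an empty partition on {len(ids)} phages"
        )
    return CorpusSplit(train_ids=sorted(train), test_ids=sorted(test), seed=seed, fraction=fraction)


def write_split(split: CorpusSplit, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("phage_id\tpartition\n")
        for pid in split.train_ids:
            fh.write(f"{pid}\ttrain\n")
        for pid in split.test_ids:
            fh.write(f"{pid}\ttest\n")


def read_split(path: str | Path, seed: int = -1, fraction: float = 0.8) -> CorpusSplit:
    train: list[str] = []
    test: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or (lineno == 1 and line.startswith("phage_id")):
                continue
            pid, part = line.split("\t")
            (train if part == "train" else test).append(pid)
    return CorpusSplit(train_ids=train, test_ids=test, seed=seed, fraction=fraction)
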