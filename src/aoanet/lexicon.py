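"""Synthetic slot-structured lexica with controllable quasi-regularity.

The training materials are artificial monosyllables laid out over four
positional slots: slots 1-2 hold onset letters, slot 3 the vowel/body and
slot 4 the coda (slots 3-4 together form the rime).  Spelling slots index a
letter alphabet (default 33 symbols) and pronunciation slots a phoneme
alphabet (default 28 symbols); unused slots are BLANK.

Two spelling-to-sound regimes are supported:

``quasi_regular``
    a deterministic per-slot rule table maps letters to phonemes; a
    configurable fraction of items deviates from the rule in the body->rime
    mapping, giving a mostly rule-governed ("deep") orthography.
``arbitrary``
    pronunciations are drawn independently of spellings, emulating the
    unstructured random pattern sets used in earlier modelling work.

Items carry a grade of first appearance (1-5), an integer frequency weight
and a spelling-neighbourhood consistency count (Coltheart-N analogue at slot
granularity).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

#: slot value marking an empty position
BLANK: int = -1

#: number of positional slots per word
N_SLOTS: int = 4

#: per-grade group sizes of the study materials
DEFAULT_GROUP_SIZES: Dict[int, int] = {1: 82, 2: 62, 3: 56, 4: 49, 5: 78}

DEFAULT_N_LETTERS: int = 33
DEFAULT_N_PHONEMES: int = 28

Slots = Tuple[int, int, int, int]


@dataclass(frozen=True)
class WordItem:
    """A single lexical item: slot spelling, slot pronunciation, covariates."""

    word_id: str
    spelling: Slots
    pronunciation: Slots
    grade: int
    frequency: int
    consistency: int = 0

    def __post_init__(self) -> None:
        for name, slots in (("spelling", self.spelling), ("pronunciation", self.pronunciation)):
            if len(slots) != N_SLOTS:
                raise ValueError(f"{name} of {self.word_id!r} must have exactly {N_SLOTS} slots")
            if all(s == BLANK for s in slots):
                raise ValueError(f"{name} of {self.word_id!r} has no non-BLANK slot")
            if any(s != BLANK and s < 0 for s in slots):
                raise ValueError(f"{name} of {self.word_id!r} has a negative symbol index")
        if not 1 <= self.grade <= 5:
            raise ValueError(f"grade of {self.word_id!r} must be in 1..5")
        if self.frequency < 1:
            raise ValueError(f"frequency of {self.word_id!r} must be a positive integer")
        if self.consistency < 0:
            raise ValueError(f"consistency of {self.word_id!r} must be nonnegative")


@dataclass(frozen=True)
class LexiconConfig:
    """Generation parameters for a synthetic lexicon."""

    group_sizes: Mapping[int, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_letters: int = DEFAULT_N_LETTERS
    n_phonemes: int = DEFAULT_N_PHONEMES
    mapping_mode: str = "quasi_regular"  # or "arbitrary"
    inconsistency_rate: float = 0.2
    frequency_geom_p: float = 0.5  # geometric draw; most words get frequency 1-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mapping_mode not in ("quasi_regular", "arbitrary"):
            raise ValueError(f"unknown mapping_mode {self.mapping_mode!r}")
        if not 0.0 <= self.inconsistency_rate <= 1.0:
            raise ValueError("inconsistency_rate must lie in [0, 1]")
        if not 0.0 < self.frequency_geom_p <= 1.0:
            raise ValueError("frequency_geom_p must lie in (0, 1]")
        if self.n_letters < 2 or self.n_phonemes < 2:
            raise ValueError("alphabets need at least 2 symbols")
        if not self.group_sizes:
            raise ValueError("group_sizes must be nonempty")
        for g, n in self.group_sizes.items():
            if not 1 <= g <= 5:
                raise ValueError("grades must lie in 1..5")
            if n < 1:
                raise ValueError("every group size must be >= 1")

    @property
    def total(self) -> int:
        return sum(self.group_sizes.values())


@dataclass
class Lexicon:
    """An ordered collection of :class:`WordItem` plus its alphabet sizes."""

    items: List[WordItem]
    n_letters: int = DEFAULT_N_LETTERS
    n_phonemes: int = DEFAULT_N_PHONEMES

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[WordItem]:
        return iter(self.items)

    def __getitem__(self, i: int) -> WordItem:
        return self.items[i]

    @property
    def word_ids(self) -> List[str]:
        return [it.word_id for it in self.items]

    def by_grade(self, grade: int) -> List[WordItem]:
        return [it for it in self.items if it.grade == grade]

    def subset(self, word_ids: Sequence[str]) -> "Lexicon":
        wanted = set(word_ids)
        return Lexicon(
            [it for it in self.items if it.word_id in wanted],
            n_letters=self.n_letters,
            n_phonemes=self.n_phonemes,
        )

    def get(self, word_id: str) -> WordItem:
        for it in self.items:
            if it.word_id == word_id:
                return it
        raise KeyError(word_id)

    # ------------------------------------------------------------------ I/O

    _COLUMNS = (
        ["word_id"]
        + [f"slot{i}" for i in range(1, 5)]
        + [f"pslot{i}" for i in range(1, 5)]
        + ["grade", "frequency", "consistency"]
    )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for it in self.items:
            row: dict = {"word_id": it.word_id}
            for i, s in enumerate(it.spelling, start=1):
                row[f"slot{i}"] = "-" if s == BLANK else str(s)
            for i, s in enumerate(it.pronunciation, start=1):
                row[f"pslot{i}"] = "-" if s == BLANK else str(s)
            row.update(grade=it.grade, frequency=it.frequency, consistency=it.consistency)
            rows.append(row)
        return pd.DataFrame(rows, columns=self._COLUMNS)

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)

    def to_csv_string(self) -> str:
        buf = io.StringIO()
        self.to_csv(buf)
        return buf.getvalue()

    @classmethod
    def from_csv(
        cls,
        path_or_buf,
        n_letters: int = DEFAULT_N_LETTERS,
        n_phonemes: int = DEFAULT_N_PHONEMES,
    ) -> "Lexicon":
        df = pd.read_csv(path_or_buf, dtype=str)
        missing = [c for c in cls._COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"lexicon CSV is missing columns: {missing}")

        def slot(v: str) -> int:
            return BLANK if v == "-" else int(v)

        items = [
            WordItem(
                word_id=str(r["word_id"]),
                spelling=tuple(slot(r[f"slot{i}"]) for i in range(1, 5)),
                pronunciation=tuple(slot(r[f"pslot{i}"]) for i in range(1, 5)),
                grade=int(r["grade"]),
                frequency=int(r["frequency"]),
                consistency=int(r["consistency"]),
            )
            for _, r in df.iterrows()
        ]
        return cls(items, n_letters=n_letters, n_phonemes=n_phonemes)


# --------------------------------------------------------------------------
# generation


def _rule_tables(rng: np.random.Generator, n_letters: int, n_phonemes: int):
    """Per-slot deterministic letter->phoneme rule table and a deviant table.

    The deviant table disagrees with the rule table for every letter, so an
    inconsistent item's rime pronunciation never coincides with the regular
    one by accident.
    """
    rule = rng.integers(0, n_phonemes, size=(N_SLOTS, n_letters))
    offset = rng.integers(1, n_phonemes, size=(N_SLOTS, n_letters))
    deviant = (rule + offset) % n_phonemes
    return rule, deviant


#: fraction of words with a second onset letter / with a coda
P_ONSET2: float = 0.4
P_CODA: float = 0.6


def _group_shapes(rng: np.random.Generator, n: int) -> List[Tuple[bool, bool]]:
    """Slot-occupancy shapes (has onset-2, has coda) for one grade group.

    Counts are exact per group rather than Bernoulli draws, so every grade
    group has the same word-length composition: the groups are matched on
    length the way the study materials were matched on the non-AoA factors.
    """
    n2 = int(np.floor(P_ONSET2 * n + 0.5))
    n4 = int(np.floor(P_CODA * n + 0.5))
    has2 = np.zeros(n, dtype=bool)
    has2[rng.choice(n, size=n2, replace=False)] = True
    has4 = np.zeros(n, dtype=bool)
    has4[rng.choice(n, size=n4, replace=False)] = True
    return list(zip(has2.tolist(), has4.tolist()))


def _draw_spelling(rng: np.random.Generator, n_letters: int, shape: Tuple[bool, bool]) -> Slots:
    """One monosyllable-shaped spelling C(C)V(C) with the given occupancy."""
    has2, has4 = shape
    s1 = int(rng.integers(0, n_letters))
    s2 = int(rng.integers(0, n_letters)) if has2 else BLANK
    s3 = int(rng.integers(0, n_letters))
    s4 = int(rng.integers(0, n_letters)) if has4 else BLANK
    return (s1, s2, s3, s4)


def generate_lexicon(config: LexiconConfig) -> Lexicon:
    """Generate a synthetic lexicon; identical config+seed gives identical output.

    Spellings are unique across the lexicon.  In quasi_regular mode each
    item's pronunciation is the rule table applied slot-wise to its spelling,
    except that a Bernoulli(inconsistency_rate) subset instead takes the
    deviant body->rime mapping on slots 3-4.  In arbitrary mode the
    pronunciation is drawn independently of the spelling.
    """
    rng = np.random.default_rng(config.seed)
    rule, deviant = _rule_tables(rng, config.n_letters, config.n_phonemes)

    total = config.total
    seen: set = set()
    items: List[WordItem] = []
    idx = 0
    for grade in sorted(config.group_sizes):
        n_g = config.group_sizes[grade]
        shapes = _group_shapes(rng, n_g)
        # Stratified inconsistency: each grade group carries the same
        # proportion of rule-deviating items, emulating materials matched on
        # consistency across the grade groups.
        n_dev = int(np.floor(config.inconsistency_rate * n_g + 0.5))
        deviates = np.zeros(n_g, dtype=bool)
        deviates[rng.choice(n_g, size=n_dev, replace=False)] = True
        for j in range(n_g):
            attempts = 0
            while True:
                attempts += 1
                if attempts > 1000:
                    raise ValueError(
                        "cannot draw another unique spelling; alphabet capacity exceeded"
                    )
                sp = _draw_spelling(rng, config.n_letters, shapes[j])
                if sp not in seen:
                    seen.add(sp)
                    break
            if config.mapping_mode == "quasi_regular":
                pron = [BLANK if s == BLANK else int(rule[k, s]) for k, s in enumerate(sp)]
                if deviates[j]:
                    for k in (2, 3):  # body and coda slots = the rime
                        if sp[k] != BLANK:
                            pron[k] = int(deviant[k, sp[k]])
            else:  # arbitrary: spelling and sound unrelated
                pron = [
                    int(rng.integers(0, config.n_phonemes)) if sp[k] != BLANK else BLANK
                    for k in range(N_SLOTS)
                ]
            freq = int(rng.geometric(config.frequency_geom_p))
            items.append(
                WordItem(
                    word_id=f"g{grade}w{idx:04d}",
                    spelling=sp,
                    pronunciation=tuple(pron),
                    grade=grade,
                    frequency=freq,
                )
            )
            idx += 1

    return compute_consistency(
        Lexicon(items, n_letters=config.n_letters, n_phonemes=config.n_phonemes)
    )


def regularity_fraction(lexicon: Lexicon, config: LexiconConfig) -> float:
    """Fraction of items whose pronunciation equals the rule table applied
    to their spelling (requires the generating config for the rule table)."""
    rng = np.random.default_rng(config.seed)
    rule, _ = _rule_tables(rng, config.n_letters, config.n_phonemes)
    n_ok = 0
    for it in lexicon:
        expected = tuple(
            BLANK if s == BLANK else int(rule[k, s]) for k, s in enumerate(it.spelling)
        )
        n_ok += expected == it.pronunciation
    return n_ok / len(lexicon)


# --------------------------------------------------------------------------
# consistency


def compute_consistency(lexicon: Lexicon) -> Lexicon:
    """Fill each item's consistency: the number of other items whose spelling
    differs in exactly one slot (a slot-granular Coltheart-N).

    The neighbour relation is symmetric, so the consistency column always
    sums to an even number.
    """
    if len(lexicon) == 0:
        raise ValueError("lexicon is empty")
    S = np.array([it.spelling for it in lexicon.items])  # (n, 4), BLANK = -1
    diff = (S[:, None, :] != S[None, :, :]).sum(axis=2)  # pairwise slot differences
    counts = ((diff == 1).sum(axis=1)).astype(int)  # diagonal is 0 differences
    items = [replace(it, consistency=int(c)) for it, c in zip(lexicon.items, counts)]
    return Lexicon(items, n_letters=lexicon.n_letters, n_phonemes=lexicon.n_phonemes)
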