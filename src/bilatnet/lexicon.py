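"""Synthetic training environment: phoneme inventory, CVC lexicon, nonwords.

The repetition task operates over monosyllabic consonant-vowel-consonant
(CVC) words.  Each phoneme is coded as a 25-dimensional binary phonetic
feature vector; a word is three such vectors presented sequentially.  The
lexicon holds 100 high-frequency (HF) and 100 low-frequency (LF) words plus
25 nonword probes formed by single-phoneme substitution, and words are
presented for training with probability proportional to log-compressed
token frequency.

The feature code is synthetic: one feature is a consonant/vowel class
indicator and the remaining 24 are random bits, constrained to be pairwise
distinct across the inventory.  This preserves the dimensionality and the
within-class similarity structure the model needs without committing to any
particular phonetic theory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

N_FEATURES = 25
#: index of the consonant/vowel indicator feature (1 = vowel)
VOWEL_FEATURE = 0

_CONSONANT_SYMBOLS = [
    "p", "t", "k", "b", "d", "g", "f", "v", "s", "z",
    "m", "n", "l", "r", "w", "j", "h", "x",
]
_VOWEL_SYMBOLS = ["a", "e", "i", "o", "u", "y"]

# token-frequency bands for the two frequency classes (inclusive)
HF_RANGE = (200, 2000)
LF_RANGE = (1, 20)

N_WORDS_PER_CLASS = 100
N_NONWORDS = 25


@dataclass(frozen=True)
class Phoneme:
    symbol: str
    klass: str  # "consonant" | "vowel"
    features: np.ndarray  # (25,) binary

    def __post_init__(self):
        if self.features.shape != (N_FEATURES,):
            raise ValueError(f"feature vector must have {N_FEATURES} entries")


class PhonemeInventory:
    """The alphabet of the phonological code.

    Parameters
    ----------
    phonemes
        Phoneme records; feature vectors must be pairwise distinct.
    """

    def __init__(self, phonemes: list[Phoneme]):
        self.phonemes = list(phonemes)
        self._by_symbol = {p.symbol: p for p in self.phonemes}
        if len(self._by_symbol) != len(self.phonemes):
            raise ValueError("duplicate phoneme symbols")
        feats = self.feature_matrix()
        if len({tuple(row) for row in feats}) != len(self.phonemes):
            raise ValueError("feature vectors are not pairwise distinct")

    @property
    def consonants(self) -> list[str]:
        return [p.symbol for p in self.phonemes if p.klass == "consonant"]

    @property
    def vowels(self) -> list[str]:
        return [p.symbol for p in self.phonemes if p.klass == "vowel"]

    @property
    def symbols(self) -> list[str]:
        return [p.symbol for p in self.phonemes]

    def __len__(self) -> int:
        return len(self.phonemes)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._by_symbol

    def __getitem__(self, symbol: str) -> Phoneme:
        try:
            return self._by_symbol[symbol]
        except KeyError:
            raise KeyError(f"unknown phoneme symbol: {symbol!r}") from None

    def feature_matrix(self) -> np.ndarray:
        """All feature vectors stacked in inventory order, shape (n, 25)."""
        return np.stack([p.features for p in self.phonemes])

    def klass_of(self, symbol: str) -> str:
        return self[symbol].klass

    # -- serialization ----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            p.symbol: {"klass": p.klass, "features": p.features.tolist()}
            for p in self.phonemes
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PhonemeInventory":
        payload = json.loads(Path(path).read_text())
        phonemes = [
            Phoneme(sym, rec["klass"], np.asarray(rec["features"], dtype=float))
            for sym, rec in payload.items()
        ]
        return cls(phonemes)


@dataclass(frozen=True)
class Word:
    phonemes: tuple[str, str, str]  # (C, V, C)
    freq_class: str  # "HF" | "LF"
    token_freq: int


@dataclass
class Lexicon:
    """200 CVC words (100 HF + 100 LF), 25 nonword probes, sampling law."""

    words: list[Word]
    nonwords: list[tuple[str, str, str]]
    inventory: PhonemeInventory
    presentation_probs: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.presentation_probs is None:
            self.presentation_probs = presentation_probabilities(self)

    @property
    def hf_indices(self) -> np.ndarray:
        return np.array([i for i, w in enumerate(self.words) if w.freq_class == "HF"])

    @property
    def lf_indices(self) -> np.ndarray:
        return np.array([i for i, w in enumerate(self.words) if w.freq_class == "LF"])

    def word_triples(self) -> list[tuple[str, str, str]]:
        return [w.phonemes for w in self.words]

    # -- serialization ----------------------------------------------------
    def to_tsv(self, words_path: str | Path, nonwords_path: str | Path) -> None:
        rows = [
            {"word_id": i, "p1": w.phonemes[0], "p2": w.phonemes[1],
             "p3": w.phonemes[2], "freq_class": w.freq_class,
             "token_freq": w.token_freq}
            for i, w in enumerate(self.words)
        ]
        pd.DataFrame(rows).to_csv(words_path, sep="\t", index=False)
        nw = [{"nonword_id": i, "p1": t[0], "p2": t[1], "p3": t[2]}
              for i, t in enumerate(self.nonwords)]
        pd.DataFrame(nw).to_csv(nonwords_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, words_path: str | Path, nonwords_path: str | Path,
                 inventory: PhonemeInventory) -> "Lexicon":
        wdf = pd.read_csv(words_path, sep="\t").sort_values("word_id")
        words = [
            Word((r.p1, r.p2, r.p3), r.freq_class, int(r.token_freq))
            for r in wdf.itertuples()
        ]
        ndf = pd.read_csv(nonwords_path, sep="\t").sort_values("nonword_id")
        nonwords = [(r.p1, r.p2, r.p3) for r in ndf.itertuples()]
        return cls(words, nonwords, inventory)


def build_inventory(seed: int, n_consonants: int = 18, n_vowels: int = 6,
                    extra_bit_p: float = 0.15) -> PhonemeInventory:
    """Generate a synthetic phoneme inventory with binary feature vectors.

    The code mimics a distinctive-feature phonetic system, where similar
    phonemes share most features (minimal pairs such as voiced/voiceless
    stops differ in a single feature).  Layout of the 25 features:

    ========  =================================================
    0         consonant/vowel class indicator (1 = vowel)
    1-6       consonant place of articulation (one-hot)
    7-9       consonant manner (stop / fricative / sonorant)
    10        voicing (vowels always 1)
    11-13     vowel height (one-hot)
    14-16     vowel backness (one-hot)
    17        lip rounding (back vowels)
    18-24     sparse redundant "acoustic" bits, each on with
              probability ``extra_bit_p``
    ========  =================================================

    Consonants are distinct (place, manner, voicing) triples drawn from
    the 6 x 3 x 2 grid; vowels are distinct (height, backness) pairs.
    Deterministic in ``seed``.
    """
    if n_consonants > len(_CONSONANT_SYMBOLS) or n_vowels > len(_VOWEL_SYMBOLS):
        raise ValueError("not enough phoneme symbols for requested inventory size")
    if n_consonants > 36 or n_vowels > 9:
        raise ValueError("articulatory grid supports at most 36 consonants "
                         "and 9 vowels")
    rng = np.random.default_rng(seed)
    phonemes = []

    cons_grid = [(p, m, v) for p in range(6) for m in range(3) for v in range(2)]
    cons_pick = rng.permutation(len(cons_grid))[:n_consonants]
    for i, symbol in zip(cons_pick, _CONSONANT_SYMBOLS[:n_consonants]):
        place, manner, voice = cons_grid[i]
        feats = np.zeros(N_FEATURES)
        feats[1 + place] = 1.0
        feats[7 + manner] = 1.0
        feats[10] = float(voice)
        feats[18:] = rng.random(7) < extra_bit_p
        phonemes.append(Phoneme(symbol, "consonant", feats))

    vowel_grid = [(h, b) for h in range(3) for b in range(3)]
    vowel_pick = rng.permutation(len(vowel_grid))[:n_vowels]
    for i, symbol in zip(vowel_pick, _VOWEL_SYMBOLS[:n_vowels]):
        height, back = vowel_grid[i]
        feats = np.zeros(N_FEATURES)
        feats[VOWEL_FEATURE] = 1.0
        feats[10] = 1.0  # vowels are voiced
        feats[11 + height] = 1.0
        feats[14 + back] = 1.0
        feats[17] = 1.0 if back == 2 else 0.0
        feats[18:] = rng.random(7) < extra_bit_p
        phonemes.append(Phoneme(symbol, "vowel", feats))
    return PhonemeInventory(phonemes)


def generate_lexicon(inventory: PhonemeInventory, seed: int,
                     n_per_class: int = N_WORDS_PER_CLASS,
                     n_nonwords: int = N_NONWORDS) -> Lexicon:
    """Sample the CVC word corpus with two-band token frequencies.

    HF token frequencies are uniform on ``HF_RANGE``, LF on ``LF_RANGE``;
    the bands are disjoint so every HF word outranks every LF word.
    Raises if the inventory cannot supply ``2 * n_per_class`` distinct
    triples.
    """
    rng = np.random.default_rng(seed)
    cons, vows = inventory.consonants, inventory.vowels
    n_possible = len(cons) * len(vows) * len(cons)
    n_words = 2 * n_per_class
    if n_words > n_possible:
        raise ValueError(
            f"cannot draw {n_words} distinct CVC words from "
            f"{len(cons)}x{len(vows)}x{len(cons)} = {n_possible} combinations")
    triples: list[tuple[str, str, str]] = []
    seen: set[tuple[str, str, str]] = set()
    while len(triples) < n_words:
        t = (cons[rng.integers(len(cons))], vows[rng.integers(len(vows))],
             cons[rng.integers(len(cons))])
        if t not in seen:
            seen.add(t)
            triples.append(t)
    words = []
    for i, t in enumerate(triples):
        if i < n_per_class:
            freq = int(rng.integers(HF_RANGE[0], HF_RANGE[1] + 1))
            words.append(Word(t, "HF", freq))
        else:
            freq = int(rng.integers(LF_RANGE[0], LF_RANGE[1] + 1))
            words.append(Word(t, "LF", freq))
    lex = Lexicon(words, [], inventory)
    lex.nonwords = generate_nonwords(lex, inventory, seed, n_nonwords)
    return lex


def generate_nonwords(lexicon: Lexicon, inventory: PhonemeInventory,
                      seed: int, n: int = N_NONWORDS) -> list[tuple[str, str, str]]:
    """Create nonword probes by single-phoneme substitution.

    Each nonword differs from some lexicon word in exactly one slot, keeps
    the C-V-C class structure, and matches no word in the lexicon.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    word_set = set(w.phonemes for w in lexicon.words)
    cons, vows = inventory.consonants, inventory.vowels
    nonwords: list[tuple[str, str, str]] = []
    seen: set[tuple[str, str, str]] = set()
    attempts = 0
    while len(nonwords) < n:
        attempts += 1
        if attempts > 10000 * n:
            raise RuntimeError(f"could not find {n} nonword neighbours")
        src = lexicon.words[rng.integers(len(lexicon.words))].phonemes
        slot = int(rng.integers(3))
        pool = vows if slot == 1 else cons
        repl = pool[rng.integers(len(pool))]
        if repl == src[slot]:
            continue
        cand = tuple(repl if i == slot else src[i] for i in range(3))
        if cand in word_set or cand in seen:
            continue
        seen.add(cand)
        nonwords.append(cand)  # type: ignore[arg-type]
    return nonwords


def encode(triple: tuple[str, str, str],
           inventory: PhonemeInventory) -> np.ndarray:
    """Feature-encode a phoneme triple as a (3, 25) matrix."""
    return np.stack([inventory[s].features for s in triple])


def encode_words(triples: list[tuple[str, str, str]],
                 inventory: PhonemeInventory) -> np.ndarray:
    """Encode many triples at once, shape (n, 3, 25)."""
    return np.stack([encode(t, inventory) for t in triples])


def presentation_probabilities(lexicon: Lexicon) -> np.ndarray:
    """Log-compressed frequency-weighted sampling law, p(w) ∝ log(1 + f_w)."""
    freqs = np.array([w.token_freq for w in lexicon.words], dtype=float)
    if np.any(freqs <= 0):
        raise ValueError("token frequencies must be positive")
    weights = np.log1p(freqs)
    return weights / weights.sum()
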