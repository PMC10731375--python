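"""Packaged data files: name dictionary fixture, stopwords, lyric phrases."""

from __future__ import annotations

import csv
from functools import lru_cache
from importlib import resources
from pathlib import Path

_DATA = resources.files("lonelytext") / "data"

NAMES_FIXTURE = "names_fixture.csv"
STOPWORDS_FILE = "stopwords_en.txt"
LYRICS_FILE = "lyric_phrases_synthetic.txt"


def data_path(name: str) -> Path:
    return Path(str(_DATA / name))


def normalize_token(token: str) -> str:
    """Case-fold and strip non-alphanumeric characters (same rule as the
    tweet tokenizer, so list entries match tokenized text)."""
    return "".join(ch for ch in token.casefold() if ch.isalnum())


@lru_cache(maxsize=1)
def load_stopwords() -> frozenset[str]:
    words = set()
    with open(data_path(STOPWORDS_FILE), encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            norm = normalize_token(line)
            if norm:
                words.add(norm)
    return frozenset(words)


@lru_cache(maxsize=1)
def load_default_lyrics() -> tuple[str, ...]:
    phrases = []
    with open(data_path(LYRICS_FILE), encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                phrases.append(line)
    return tuple(phrases)


@lru_cache(maxsize=1)
def load_name_table() -> dict[str, set[str]]:
    """Fixture name -> {'F'} / {'M'} / {'F','M'} attestation sets."""
    table: dict[str, set[str]] = {}
    with open(data_path(NAMES_FIXTURE), encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            table.setdefault(row["name"].strip().casefold(), set()).add(
                row["gender"].strip().upper())
    return table
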