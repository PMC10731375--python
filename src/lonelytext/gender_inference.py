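"""Name-dictionary gender inference from free-form profile names.

A user is labelled female or male only when the candidate name token is
attested for exactly one gender across the merged dictionaries (baby-name
registries and similar lists with a ``name,gender[,count]`` CSV schema);
users with no candidate, no dictionary entry, or conflicting attestations
stay ``unknown`` and are discarded downstream.  Non-binary genders cannot
be inferred from such listings — a documented limitation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .corpus import TweetRecord
from .resources import data_path, NAMES_FIXTURE

FEMALE = "female"
MALE = "male"
UNKNOWN = "unknown"

_GENDER_CODES = {"F": FEMALE, "M": MALE}


class NameDictionaryError(ValueError):
    """Malformed name-list row; carries file and 1-based row number."""


@dataclass
class NameDictionary:
    """Normalized name -> set of gender attestations, with per-source
    provenance (which file attested which code)."""

    attestations: dict[str, set[str]] = field(default_factory=dict)
    provenance: dict[str, dict[str, set[str]]] = field(default_factory=dict)

    def add(self, name: str, code: str, source: str) -> None:
        norm = normalize_name(name)
        if not norm:
            return
        self.attestations.setdefault(norm, set()).add(code)
        self.provenance.setdefault(norm, {}).setdefault(source, set()).add(code)

    def genders_for(self, name: str) -> set[str]:
        return self.attestations.get(normalize_name(name), set())

    def __len__(self) -> int:
        return len(self.attestations)


def normalize_name(name: str) -> str:
    """Canonical form: case-folded, ASCII letters only."""
    return "".join(ch for ch in name.casefold() if "a" <= ch <= "z")


def load_name_dictionary(csv_paths: Sequence[str | Path] | str | Path
                         ) -> NameDictionary:
    """Union of attestations across ``name,gender[,count]`` CSV files."""
    if isinstance(csv_paths, (str, Path)):
        csv_paths = [csv_paths]
    dictionary = NameDictionary()
    for path in csv_paths:
        path = Path(path)
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                continue
            for row_no, row in enumerate(reader, start=2):
                code = (row.get("gender") or "").strip().upper()
                if code not in _GENDER_CODES:
                    raise NameDictionaryError(
                        f"{path}:{row_no}: unknown gender code {code!r} "
                        "(expected F or M)")
                dictionary.add(row.get("name") or "", code, source=path.name)
    return dictionary


def default_name_dictionary() -> NameDictionary:
    return load_name_dictionary(data_path(NAMES_FIXTURE))


def extract_candidate_name(profile_name_field: str) -> str | None:
    """First whitespace-delimited token that is a pure-letter name once
    decorations are stripped.

    Punctuation and symbols are removed within each token; a token whose
    remainder contains digits (or nothing) is skipped.  Honorifics are not
    treated specially, so "DR. Anya" yields "dr" — a known limitation of
    the first-token rule.
    """
    if not profile_name_field:
        return None
    for token in profile_name_field.split():
        stripped = "".join(ch for ch in token.casefold()
                           if ch.isascii() and ch.isalnum())
        if stripped and stripped.isalpha():
            return stripped
    return None


def infer_gender(dictionary: NameDictionary, profile_name_field: str) -> str:
    """female / male iff the candidate is attested for exactly that gender;
    unknown otherwise (no candidate, no entry, or ambiguous attestation)."""
    candidate = extract_candidate_name(profile_name_field)
    if candidate is None:
        return UNKNOWN
    codes = dictionary.genders_for(candidate)
    if len(codes) == 1:
        return _GENDER_CODES[next(iter(codes))]
    return UNKNOWN


def annotate_genders(tweets: Iterable[TweetRecord],
                     dictionary: NameDictionary
                     ) -> tuple[list[TweetRecord], dict[str, int]]:
    """Attach inferred gender to each tweet; drop unknown-gender users.

    Returns the annotated tweets and counts by outcome.
    """
    counts = {FEMALE: 0, MALE: 0, UNKNOWN: 0}
    cache: dict[int, str] = {}
    out = []
    for t in tweets:
        g = cache.get(t.user.id)
        if g is None:
            g = infer_gender(dictionary, t.user.name)
            cache[t.user.id] = g
        counts[g] += 1
        if g != UNKNOWN:
            out.append(t.with_gender(g))
    return out, counts
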