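"""Default stemming strategy for morphological consolidation.

Clinical-vocabulary clustering needs a stemmer that collapses whole
derivational families — *short / shorter / shorten / shortening* must share a
stem, which rules out conservative inflectional stemmers (Porter leaves both
"shorter" and "shorten" intact because its measure conditions block the
"-er"/"-en" strips on short stems).  The default here is a deterministic
iterative suffix stripper: it repeatedly removes a small ordered set of
English inflectional and derivational suffixes, then tidies a trailing "e"
and doubled final consonant, until a fixed point is reached.

Any callable ``str -> str`` can replace it; determinism and idempotence are
the only requirements the clustering code relies on.
"""

from __future__ import annotations

from typing import Callable, Protocol

VOWELS = set("aeiouy")

# Longest-match-first within each pass; order matters for e.g. "ings" vs "s".
_SUFFIXES = (
    "ations",
    "ation",
    "ingly",
    "ings",
    "ing",
    "edly",
    "ied",
    "ies",
    "ed",
    "en",
    "ers",
    "er",
    "est",
    "es",
    "s",
    "ness",
    "ity",
    "ally",
    "al",
    "ly",
)

#: Minimum stem length left behind by any strip; mirrors the 4-letter prefix
#: rule used for cluster grouping so stripping can never cross prefix groups.
MIN_STEM = 4


class Stemmer(Protocol):
    def __call__(self, token: str) -> str: ...


def _has_vowel(s: str) -> bool:
    return any(c in VOWELS for c in s)


def _strip_once(word: str) -> str:
    for suf in _SUFFIXES:
        if word.endswith(suf):
            rest = word[: -len(suf)]
            if len(rest) >= MIN_STEM and _has_vowel(rest):
                return rest
    return word


def suffix_stem(token: str) -> str:
    """Stem a lowercase letters-only token (idempotent, deterministic)."""
    word = token
    while True:
        prev = word
        word = _strip_once(word)
        # silent-e and consonant doubling left behind by the strips:
        # increase/increased -> increas, run/running -> run
        if len(word) > MIN_STEM and word.endswith("e"):
            word = word[:-1]
        if len(word) > MIN_STEM and word[-1] == word[-2] and word[-1] not in VOWELS:
            word = word[:-1]
        if word == prev:
            return word


#: Registry so a stemmer choice can be pinned by name in serialized artifacts.
STEMMERS: dict[str, Callable[[str], str]] = {
    "suffix-v1": suffix_stem,
    "identity": lambda t: t,
}

DEFAULT_STEMMER = "suffix-v1"
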