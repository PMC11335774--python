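"""Core morphological features and their canonical serialization.

A lexical database that disambiguates by morphology must decide which
Universal Dependencies features participate in the row key.  Keeping every
feature the parser emits would explode the number of rows (and expose parser
noise in features like ``Style``); keeping none would collapse genuinely
distinct readings.  The middle ground used here is a fixed set of eleven
"core" features: case, number and person; verb form (finiteness), mood,
tense and voice; clitic and derivation markers; and the person and number of
a possessive suffix.  Everything else (``Degree``, ``Polarity``, pronoun
subtypes, ``Style`` ...) is projected away before aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Mapping, Optional

__all__ = [
    "CoreFeatures",
    "CORE_FEATURE_KEYS",
    "FEATURE_QUERY_KEYS",
    "EMPTY_FEATS",
    "project_core_features",
]

#: UD feature name -> CoreFeatures attribute.  Possessor person/number use the
#: UD layered-feature spelling (``Person[psor]``).
_UD_TO_ATTR = {
    "Case": "case",
    "Number": "number",
    "Person": "person",
    "VerbForm": "verbform",
    "Mood": "mood",
    "Tense": "tense",
    "Voice": "voice",
    "Clitic": "clitic",
    "Derivation": "derivation",
    "Person[psor]": "posspers",
    "Number[psor]": "possnum",
}
_ATTR_TO_UD = {v: k for k, v in _UD_TO_ATTR.items()}

CORE_FEATURE_KEYS = tuple(_UD_TO_ATTR)

#: query-language key names, in canonical column order
FEATURE_QUERY_KEYS = (
    "case",
    "number",
    "person",
    "verbform",
    "mood",
    "tense",
    "voice",
    "clitic",
    "derivation",
    "posspers",
    "possnum",
)

#: serialization of an empty feature set, as in CoNLL-U
EMPTY_FEATS = "_"


@dataclass(frozen=True)
class CoreFeatures:
    """The disambiguating subset of UD morphological features.

    Two feature sets are equal iff their canonical serializations are equal;
    the serialization is the CoNLL-U convention of ``Key=Value`` pairs joined
    by ``|`` in case-insensitive alphabetical key order, with the empty set
    written as ``_``.
    """

    case: Optional[str] = None
    number: Optional[str] = None
    person: Optional[str] = None
    verbform: Optional[str] = None
    mood: Optional[str] = None
    tense: Optional[str] = None
    voice: Optional[str] = None
    clitic: Optional[str] = None
    derivation: Optional[str] = None
    posspers: Optional[str] = None
    possnum: Optional[str] = None

    def serialize(self) -> str:
        pairs = [
            (_ATTR_TO_UD[f.name], getattr(self, f.name))
            for f in fields(self)
            if getattr(self, f.name) is not None
        ]
        if not pairs:
            return EMPTY_FEATS
        pairs.sort(key=lambda kv: kv[0].lower())
        return "|".join(f"{k}={v}" for k, v in pairs)

    def as_dict(self) -> dict[str, Optional[str]]:
        """Attribute-name -> value mapping (None for absent features)."""
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.serialize()


def project_core_features(feats: Mapping[str, str]) -> CoreFeatures:
    """Project a UD feature mapping onto the eleven core features.

    Non-core keys (``Degree``, ``Polarity``, ``Style``, ``PronType`` ...) are
    discarded; an empty mapping yields the empty ``CoreFeatures``.
    """
    kwargs = {}
    for ud_key, attr in _UD_TO_ATTR.items():
        if ud_key in feats:
            kwargs[attr] = feats[ud_key]
    return CoreFeatures(**kwargs)
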