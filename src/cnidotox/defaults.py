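"""Shipped default model definitions and family rules.

The defaults are a representative, self-contained rule set: 41 toxin protein
families across the eight venom function categories, with every signature
realised as a PROSITE pattern or cysteine scaffold so the whole pipeline runs
without external HMM searches.  Both files are plain TSV and user-replaceable.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources


def _data(name: str):
    return resources.files("cnidotox").joinpath("data", name)


@lru_cache(maxsize=1)
def default_models():
    from .domains import load_models
    return load_models(_data("models.tsv"))


@lru_cache(maxsize=1)
def default_ruleset():
    from .rules import load_rules
    return load_rules(_data("rules.tsv"), default_models())
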