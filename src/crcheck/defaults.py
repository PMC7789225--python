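"""Shipped fixture loading (dictionary, terminology, rules) with caching."""
from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path

from .core_dictionary import Dictionary, load_dictionary
from .dl_engine import TBox
from .rulebase import RuleSet, compile_rules, load_rules
from .terminology import Terminology, load_terminology

_DATA = resources.files("crcheck") / "data"


def data_path(name: str) -> Path:
    return Path(str(_DATA / name))


@lru_cache(maxsize=None)
def load_default_dictionary() -> Dictionary:
    return load_dictionary(data_path("dictionary.yaml"))


def load_default_terminology() -> Terminology:
    # not cached: compilation registers defined classes on the instance
    names = ["topography.yaml", "morphology.yaml", "morph_behaviour.yaml",
             "tumour_types.yaml", "tnm.yaml", "groups.yaml"]
    return load_terminology([data_path(n) for n in names])


@lru_cache(maxsize=None)
def load_default_rules() -> RuleSet:
    return load_rules(data_path("rules.yaml"))


def build_tbox(rules_path=None, terminology_path=None) -> TBox:
    """Fresh terminology + compiled rule base (defaults when paths are None)."""
    term = (load_default_terminology() if terminology_path is None
            else load_terminology(terminology_path))
    rules = load_default_rules() if rules_path is None else load_rules(rules_path)
    return compile_rules(rules, term)


@lru_cache(maxsize=None)
def default_tbox() -> TBox:
    """Shared compiled default rule base (treat as read-only)."""
    return build_tbox()
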