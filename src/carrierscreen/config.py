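"""YAML configuration loading for filter and simulation settings.

A run's thresholds live in a small YAML document so they are versionable
alongside results; keyword overrides (e.g. from command-line flags) take
precedence over the file, which takes precedence over the defaults.

Example::

    filter:
      maf_threshold: 0.05
      maf_sources: [1000G]
      min_depth_exclusive: 10
      max_intronic_offset: 8
      exclusion_list: ["CFTR:c.3854C>T"]
    simulation:
      n_individuals: 200
      couple_fraction: 0.88
      per_gene_carrier_freq: {CFTR: 0.045}
      seed: 1
"""

from __future__ import annotations

import io
from os import PathLike

import yaml

from carrierscreen.errors import ParseError
from carrierscreen.filters import FilterConfig
from carrierscreen.simulate import SimConfig

__all__ = ["load_filter_config", "load_sim_config"]


def _load_section(source, section: str) -> dict:
    if isinstance(source, (str, PathLike)):
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    elif isinstance(source, io.IOBase):
        doc = yaml.safe_load(source)
    else:
        doc = source
    if doc is None:
        return {}
    if not isinstance(doc, dict):
        raise ParseError(f"configuration document must be a mapping, got {type(doc).__name__}")
    sub = doc.get(section, doc)
    if not isinstance(sub, dict):
        raise ParseError(f"configuration section {section!r} must be a mapping")
    return dict(sub)


def load_filter_config(source, **overrides) -> FilterConfig:
    """Build a :class:`FilterConfig` from a YAML path/handle/mapping (the
    ``filter:`` section, or the document root if absent). ``overrides``
    win over the file."""
    settings = _load_section(source, "filter")
    settings.update(overrides)
    if "exclusion_list" in settings:
        settings["exclusion_list"] = frozenset(settings["exclusion_list"])
    if "maf_sources" in settings:
        settings["maf_sources"] = tuple(settings["maf_sources"])
    try:
        return FilterConfig(**settings)
    except TypeError as exc:
        raise ParseError(f"unknown filter configuration key: {exc}") from exc


def load_sim_config(source, **overrides) -> SimConfig:
    """Build a :class:`SimConfig` from the ``simulation:`` section."""
    settings = _load_section(source, "simulation")
    settings.update(overrides)
    try:
        return SimConfig(**settings)
    except TypeError as exc:
        raise ParseError(f"unknown simulation configuration key: {exc}") from exc
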