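"""Curated model catalogue.

Ships validated model specifications as ordinary YAML files under
``neuromass/data/models`` together with a BibTeX bibliography resolving
their reference keys.  Keeping the curated models as plain spec files makes
curation mistakes test-visible: every entry is re-validated on load.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import yaml

from .errors import SpecValidationError, UnknownModelError
from .schema import DynamicsSpec, resolve_dynamics, validate_dynamics

_DESCRIPTIONS = {
    "generic2d": "Generic 2-D oscillator (FitzHugh-Nagumo generalization)",
    "jansen_rit": "Jansen-Rit three-population cortical column model",
    "reduced_wong_wang": "Reduced Wong-Wang excitatory/inhibitory mean-field model",
    "kuramoto": "Kuramoto phase oscillator",
}


def _data_dir():
    return resources.files("neuromass.data") / "models"


@dataclass(frozen=True)
class CatalogueEntry:
    name: str
    description: str
    file: str


def list_models() -> list:
    """Catalogue entries in deterministic alphabetical order."""
    out = []
    for item in sorted(_data_dir().iterdir(), key=lambda p: p.name):
        if item.name.endswith(".yaml"):
            name = item.name[: -len(".yaml")]
            out.append(CatalogueEntry(
                name=name,
                description=_DESCRIPTIONS.get(name, ""),
                file=item.name,
            ))
    return out


def get_model(name: str) -> DynamicsSpec:
    """Load, resolve and validate a catalogue model by name."""
    path = _data_dir() / f"{name}.yaml"
    try:
        text = path.read_text()
    except (FileNotFoundError, KeyError):
        raise UnknownModelError(name, [e.name for e in list_models()]) from None
    spec = DynamicsSpec.from_dict(yaml.safe_load(text))
    violations = resolve_dynamics(spec) + validate_dynamics(spec)
    if violations:
        raise SpecValidationError(violations)
    return spec


def bibliography() -> dict:
    """Reference keys -> raw BibTeX entry text from the bundled bibliography."""
    text = (_data_dir() / "references.bib").read_text()
    entries = {}
    for m in re.finditer(r"@\w+\{([^,]+),", text):
        key = m.group(1).strip()
        start = m.start()
        nxt = text.find("@", m.end())
        entries[key] = text[start: nxt if nxt != -1 else len(text)].strip()
    return entries
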