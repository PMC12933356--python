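"""Packaged reaction networks.

``formose_main`` is the 28-species / 28-step formose network: formaldehyde
dimerization via the formyl anion (R1-R3), glycolaldehyde aldol chemistry
and the C3+C2 ribose route (R4-R10), aldose-ketose tautomerization by
enolization and 1,2-hydride shift (R11-R26), and the aldotetrose
deprotonation/retroaldol cleavage that closes the autocatalytic cycle
(R27-R28).  ``formose_branched`` appends the branched-pentose shortcut
(R29-R32).  ``ab`` and ``abc`` are closed-form toy fixtures.

Each step value carries a provenance flag: ``"text"`` values are quoted in
the source narrative; ``"supplementary"`` values are transcription
estimates constrained by the text-stated aggregates (see docs/methods.md).
"""

from __future__ import annotations

from importlib import resources

from .io import load_network
from .netmodel import ReactionNetwork

__all__ = ["available", "load_packaged", "formose_main", "formose_branched"]

_NAMES = ("formose_main", "formose_branched", "ab", "abc")


def available() -> tuple[str, ...]:
    return _NAMES


def load_packaged(name: str) -> ReactionNetwork:
    if name not in _NAMES:
        raise KeyError(f"unknown packaged network {name!r}; have {_NAMES}")
    ref = resources.files("rxnkit.data") / f"{name}.json"
    with resources.as_file(ref) as path:
        return load_network(path)


def formose_main() -> ReactionNetwork:
    return load_packaged("formose_main")


def formose_branched() -> ReactionNetwork:
    return load_packaged("formose_branched")
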