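"""Nearest-neighbor energy model for intermolecular RNA:RNA duplexes.

The model scores a bimolecular helix as a sum of adjacent base-pair stacking
free energies (ΔG37, kcal/mol) plus a duplex initiation term, per-size bulge
and internal-loop penalties, and a penalty for each helix end closed by an
A·U or G·U pair.  Watson-Crick and G·U wobble pairs are allowed; there is no
intramolecular structure, no dangling ends and no coaxial stacking.

Stacking values ship as a checksummed TSV resource
(``data/stack_dg37.tsv``); loop penalties use the published initiation
tables up to size 6 with Jacobson-Stockmayer logarithmic extrapolation
above that.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources

__all__ = ["EnergyModel", "load_default_model", "STACK_TABLE_SHA256"]

#: pairs allowed in a duplex: Watson-Crick plus G·U wobble
ALLOWED_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}
)

#: sha256 of the shipped stacking table; verified at load time so a silently
#: edited parameter file is a hard error, not a quiet ranking change.
STACK_TABLE_SHA256 = "1dc8e1f0a36b7292e74f2afd6d5a52a78e29c14963c23059ca9f94d32cb7fade"
_EXPECTED_SHA256 = STACK_TABLE_SHA256

# Bulge and internal-loop initiation ΔG37 (kcal/mol) by loop size (nt).
_BULGE_INIT = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
_INTERNAL_INIT = {2: 1.5, 3: 1.6, 4: 1.7, 5: 1.8, 6: 2.0}

# Jacobson-Stockmayer coefficient 1.75 * R * T at 310.15 K.
_JS_COEFF = 1.75 * 0.0019872 * 310.15


@dataclass(frozen=True)
class EnergyModel:
    """Duplex nearest-neighbor parameter set (ΔG37 only, kcal/mol).

    Attributes
    ----------
    stack_energy:
        Mapping ``(top_dinuc, bottom_dinuc) -> ΔG37`` where ``top`` is read
        5'->3' on the query strand and ``bottom`` 3'->5' on the target, so
        ``top[k]`` pairs ``bottom[k]``.
    duplex_init:
        Bimolecular initiation penalty (+4.09 by default).
    terminal_au_gu_penalty:
        Added once per helix end whose closing pair is A·U or G·U (+0.45).
    max_loop:
        Largest combined unpaired length allowed between consecutive pairs.
    """

    stack_energy: dict[tuple[str, str], float]
    duplex_init: float = 4.09
    terminal_au_gu_penalty: float = 0.45
    max_loop: int = 15
    bulge_init: dict[int, float] = field(default_factory=lambda: dict(_BULGE_INIT))
    internal_init: dict[int, float] = field(default_factory=lambda: dict(_INTERNAL_INIT))

    def bulge_penalty(self, size: int) -> float:
        """ΔG37 of a bulge of `size` unpaired nucleotides on one strand."""
        if size < 1:
            raise ValueError(f"bulge size must be >= 1, got {size}")
        if size <= 6:
            return self.bulge_init[size]
        return self.bulge_init[6] + _JS_COEFF * math.log(size / 6.0)

    def internal_loop_penalty(self, size: int) -> float:
        """ΔG37 of an internal loop of `size` total unpaired nucleotides."""
        if size < 2:
            raise ValueError(f"internal loop size must be >= 2, got {size}")
        if size <= 6:
            return self.internal_init[size]
        return self.internal_init[6] + _JS_COEFF * math.log(size / 6.0)

    def stack(self, top: str, bottom: str) -> float:
        return self.stack_energy[(top, bottom)]

    def is_terminal_penalized(self, x: str, y: str) -> bool:
        return {x, y} in ({"A", "U"}, {"G", "U"})


def _parse_stack_table(text: str) -> dict[tuple[str, str], float]:
    table: dict[tuple[str, str], float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("top\t"):
            continue
        top, bottom, dg = line.split("\t")
        key = (top, bottom)
        if key in table:
            raise ValueError(f"duplicate stack entry {top}/{bottom}")
        table[key] = float(dg)
    return table


def _validate_table(table: dict[tuple[str, str], float]) -> None:
    # every ordered combination of two allowed pairs must be present
    expected = set()
    for x1, y1 in ALLOWED_PAIRS:
        for x2, y2 in ALLOWED_PAIRS:
            expected.add((x1 + x2, y1 + y2))
    missing = expected - set(table)
    extra = set(table) - expected
    if missing or extra:
        raise ValueError(f"stack table mismatch: missing={missing} extra={extra}")


def load_default_model(verify_checksum: bool = True) -> EnergyModel:
    """Load the shipped Turner-style ΔG37 parameter set.

    Raises
    ------
    ValueError
        If the resource file's checksum does not match the recorded digest
        (``verify_checksum=False`` skips the check) or entries are missing.
    """
    raw = resources.files("trfscreen.data").joinpath("stack_dg37.tsv").read_bytes()
    if verify_checksum:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != _EXPECTED_SHA256:
            raise ValueError(
                "stack_dg37.tsv checksum mismatch: parameter file was modified "
                f"(got {digest})"
            )
    table = _parse_stack_table(raw.decode("ascii"))
    _validate_table(table)
    return EnergyModel(stack_energy=table)
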