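"""Binding table: which processes act on which model objects.

Implicit interactions are keyed by an unordered particle-type pair plus a
cluster-scoping mode (``all`` / ``bound`` / ``unbound``), so ``(A, B)`` and
``(B, A)`` always resolve to the same entry.
"""
from __future__ import annotations

MODES = ("all", "bound", "unbound")


def pair_key(type_a: str, type_b: str) -> tuple:
    return (type_a, type_b) if type_a <= type_b else (type_b, type_a)


class BindingTable:
    """Registries of processes bound to particle types.

    - ``implicit``: (typeA, typeB, mode) -> list of Potentials
    - ``dpd``:      (typeA, typeB) -> list of DPD parameter sets
    - ``explicit``: type -> list of per-particle force generators
    """

    def __init__(self):
        self.implicit: dict[tuple, list] = {}
        self.dpd: dict[tuple, list] = {}
        self.explicit: dict[str, list] = {}

    def bind_implicit(self, type_a: str, type_b: str, potential, mode: str = "all"):
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        key = pair_key(type_a, type_b) + (mode,)
        self.implicit.setdefault(key, []).append(potential)

    def bind_dpd(self, type_a: str, type_b: str, params):
        self.dpd.setdefault(pair_key(type_a, type_b), []).append(params)

    def bind_explicit(self, type_name: str, force):
        self.explicit.setdefault(type_name, []).append(force)

    def implicit_for(self, type_a: str, type_b: str, mode: str):
        return self.implicit.get(pair_key(type_a, type_b) + (mode,), [])
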