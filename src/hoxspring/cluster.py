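"""The HoxD cluster as an ordered, editable registry of gene loci.

Loci are ordered telomeric → centromeric (Hoxd1 first) and carry a uniform
"negative charge" q; the cluster total N = Σ q is the microscale factor of the
pulling force F = P × N. The centromeric flank (containing Evx2) is modeled
solely as the boolean ``anchored`` — the fixed end of the elastic spring — and
contributes nothing to N. Deletions re-rank the survivors consecutively
(chromosome fiber continuity is restored); duplications insert copies adjacent
to their originals. Rest offsets are in nm from the telomeric end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, ParameterError

__all__ = [
    "GeneLocus",
    "HoxCluster",
    "EditSpec",
    "WILD_TYPE_GENE_NAMES",
    "WILD_TYPE_REST_LENGTH_NM",
    "wild_type_cluster",
    "apply_edit",
    "n_factor",
]

# Gene order of the complete mouse HoxD cluster, telomeric side first.
WILD_TYPE_GENE_NAMES: tuple[str, ...] = (
    "Hoxd1", "Hoxd3", "Hoxd4", "Hoxd8", "Hoxd9",
    "Hoxd10", "Hoxd11", "Hoxd12", "Hoxd13",
)
# Inactive (compacted) cluster length, nm.
WILD_TYPE_REST_LENGTH_NM = 100.0
DEFAULT_PROBES: tuple[str, ...] = ("Hoxd10", "Hoxd4")


@dataclass(frozen=True)
class GeneLocus:
    name: str
    rank: int                 # 1-based ordinal from the telomeric end
    rest_offset: float        # nm from the telomeric end at rest
    charge: float = 1.0       # dimensionless contribution to N
    is_probe: bool = False

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ParameterError(f"rank must be >= 1 (got {self.rank})")
        if self.rest_offset < 0:
            raise ParameterError(
                f"rest_offset must be >= 0 (got {self.rest_offset})")
        if self.charge <= 0:
            raise ParameterError(f"charge must be > 0 (got {self.charge})")


@dataclass(frozen=True)
class HoxCluster:
    """Ordered loci plus the centromeric anchoring state and rest length."""

    loci: tuple[GeneLocus, ...]
    anchored: bool = True
    rest_length: float = WILD_TYPE_REST_LENGTH_NM  # nm

    def __post_init__(self) -> None:
        if not self.loci:
            raise ParameterError("cluster must contain at least one locus")
        if self.rest_length <= 0:
            raise ParameterError(
                f"rest_length must be > 0 (got {self.rest_length})")
        ranks = [l.rank for l in self.loci]
        if ranks != list(range(1, len(self.loci) + 1)):
            raise ParameterError(
                f"ranks must be consecutive 1..{len(self.loci)} (got {ranks})")
        offsets = [l.rest_offset for l in self.loci]
        if any(b <= a for a, b in zip(offsets, offsets[1:])):
            raise ParameterError("rest_offsets must be strictly increasing")
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise ParameterError("locus names must be unique")

    def __len__(self) -> int:
        return len(self.loci)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(l.name for l in self.loci)

    @property
    def rest_offsets(self) -> np.ndarray:
        return np.array([l.rest_offset for l in self.loci])

    def locus(self, name: str) -> GeneLocus:
        for l in self.loci:
            if l.name == name:
                return l
        raise InputError(f"unknown locus {name!r}; cluster has {self.names}")

    def rank(self, name: str) -> int:
        return self.locus(name).rank

    @property
    def probes(self) -> tuple[str, ...]:
        return tuple(l.name for l in self.loci if l.is_probe)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "name": self.names,
                "rank": [l.rank for l in self.loci],
                "rest_offset": [l.rest_offset for l in self.loci],
                "charge": [l.charge for l in self.loci],
            }
        )


@dataclass(frozen=True)
class EditSpec:
    """A genetic-engineering manipulation of the cluster.

    ``operation`` is "delete", "duplicate" or "none" (anchor edits only).
    Duplication inserts each copy immediately centromeric to its original.
    """

    operation: str = "none"
    targets: tuple[str, ...] = field(default_factory=tuple)
    remove_centromeric_anchor: bool = False

    def __post_init__(self) -> None:
        if self.operation not in ("delete", "duplicate", "none"):
            raise ParameterError(
                f"operation must be delete|duplicate|none (got {self.operation!r})")
        object.__setattr__(self, "targets", tuple(self.targets))


def _uniform_layout(
    names: list[str],
    charges: list[float],
    probes: set[str],
    rest_length: float,
) -> tuple[GeneLocus, ...]:
    m = len(names)
    if m == 1:
        offsets = [0.0]
    else:
        offsets = list(np.linspace(0.0, rest_length, m))
    return tuple(
        GeneLocus(name=n, rank=i + 1, rest_offset=o, charge=q,
                  is_probe=n in probes)
        for i, (n, o, q) in enumerate(zip(names, offsets, charges))
    )


def wild_type_cluster(
    charge: float = 1.0,
    rest_length: float = WILD_TYPE_REST_LENGTH_NM,
    probes: tuple[str, ...] = DEFAULT_PROBES,
) -> HoxCluster:
    """The intact 9-gene HoxD cluster, anchored, equally spaced over 100 nm."""
    names = list(WILD_TYPE_GENE_NAMES)
    loci = _uniform_layout(names, [charge] * len(names), set(probes), rest_length)
    return HoxCluster(loci=loci, anchored=True, rest_length=rest_length)


def apply_edit(
    cluster: HoxCluster,
    edit: EditSpec,
    rescale_rest_length: bool = True,
) -> HoxCluster:
    """Apply a deletion/duplication and/or remove the centromeric anchor.

    Survivors are re-ranked consecutively. By default the rest length scales
    proportionally to the locus count (uniform charge density is preserved);
    with ``rescale_rest_length=False`` the rest length is kept fixed.
    """
    names = list(cluster.names)
    unknown = [t for t in edit.targets if t not in names]
    if unknown:
        raise InputError(
            f"edit targets not in cluster: {unknown}; cluster has {tuple(names)}")

    by_name = {l.name: l for l in cluster.loci}
    if edit.operation == "delete" and edit.targets:
        kept = [n for n in names if n not in set(edit.targets)]
        if not kept:
            raise InputError("cannot delete every locus in the cluster")
        new_names = kept
    elif edit.operation == "duplicate" and edit.targets:
        new_names = []
        for n in names:
            new_names.append(n)
            if n in set(edit.targets):
                copy = f"{n}_dup"
                while copy in names or copy in new_names:
                    copy += "b"
                new_names.append(copy)
                by_name[copy] = by_name[n]
        if len(new_names) == len(names):  # pragma: no cover - guarded above
            raise InputError("duplication produced no new loci")
    else:
        new_names = names

    m_old, m_new = len(names), len(new_names)
    rest = cluster.rest_length * (m_new / m_old if rescale_rest_length else 1.0)
    charges = [by_name[n].charge for n in new_names]
    probes = {n for n in new_names if n in by_name and by_name[n].is_probe
              and not n.endswith("_dup")}
    anchored = cluster.anchored and not edit.remove_centromeric_anchor
    return HoxCluster(
        loci=_uniform_layout(new_names, charges, probes, rest),
        anchored=anchored,
        rest_length=rest,
    )


def n_factor(cluster: HoxCluster) -> float:
    """Total cluster charge N = Σ q; with uniform q = 1 this is the gene count."""
    return float(sum(l.charge for l in cluster.loci))
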