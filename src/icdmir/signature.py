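"""ICD-specific signature selection and set-intersection analysis.

A feature is *called* up (down) in one contrast when its signed fold change
reaches +1.3 (-1.3) AND its p-value is at most 0.05; boundary values are
significant, and a missing fold change or p-value means "no call".  Both
conditions are required: a tiny p-value with |fc| < 1.3 is still no call.

The ICD signature collects features consistently regulated by the ICD
inducers (DXR and RA/IFNα) in both cell lines but not by gamma irradiation.
Two readings of "regulated by the ICD inducers" are supported:

``inducer_rule="any"`` (default)
    the feature is called in the same direction by at least one ICD inducer
    in each cell line — the selection described by the published contrast
    table captions ("significantly different in DXR- or RA/IFNα-treated
    samples ... in both cell lines"), and the only rule consistent with every
    printed table row;
``inducer_rule="all"``
    the feature is called in the same direction in all four ICD contrasts.

The gamma-irradiation exclusion is direction-specific by default: a feature
is excluded from the down branch only by a *down* call under gIrr (a feature
moving the opposite way under irradiation stays in, as the published tables
do for a miRNA down-signature member with a significant gIrr up call).
``strict_girr=True`` instead excludes on any gIrr call.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import ContrastError, ParameterError
from .io import CELL_LINES, ICD_TREATMENTS, ContrastTable

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DifferentialCall:
    """Direction call for one feature in one contrast."""

    feature_id: str
    cell_line: str
    treatment: str
    direction: str  # "up" | "down" | "ns"
    fc_min: float = 1.3
    alpha: float = 0.05


def call_differential(
    signed_fc: float | None,
    p: float | None,
    fc_min: float = 1.3,
    alpha: float = 0.05,
) -> str:
    """Classify one (signed fc, p) pair as ``"up"``, ``"down"`` or ``"ns"``.

    Requires BOTH |signed fc| >= fc_min and p <= alpha; boundary values are
    significant.  Missing fc or p yields ``"ns"``.
    """
    if fc_min < 1:
        raise ParameterError(f"fc_min must be >= 1, got {fc_min}")
    if not (0 <= alpha <= 1):
        raise ParameterError(f"alpha must lie in [0, 1], got {alpha}")
    if signed_fc is None or p is None or pd.isna(signed_fc) or pd.isna(p):
        return "ns"
    if p > alpha:
        return "ns"
    if signed_fc >= fc_min:
        return "up"
    if signed_fc <= -fc_min:
        return "down"
    return "ns"


@dataclass
class ICDSignature:
    """Up/down feature sets surviving the ICD intersection/exclusion rule.

    ``provenance`` holds the six per-contrast direction calls for every
    feature that was evaluated (selected or not).
    """

    up: set[str] = field(default_factory=set)
    down: set[str] = field(default_factory=set)
    provenance: pd.DataFrame | None = None

    @property
    def members(self) -> set[str]:
        return self.up | self.down

    def direction_of(self, feature_id: str) -> str:
        if feature_id in self.up:
            return "up"
        if feature_id in self.down:
            return "down"
        return "ns"


def _contrast_calls(
    table: ContrastTable,
    fc_min: float,
    alpha: float,
    cell_lines: tuple[str, ...],
    treatments: tuple[str, ...],
) -> pd.DataFrame:
    """Direction calls for every feature × (cell line, treatment)."""
    cols = {}
    for line in cell_lines:
        for treatment in treatments:
            cols[(line, treatment)] = [
                call_differential(
                    table.fc(f, line, treatment),
                    table.p(f, line, treatment),
                    fc_min=fc_min,
                    alpha=alpha,
                )
                for f in table.features
            ]
    calls = pd.DataFrame(cols, index=table.features)
    calls.columns = pd.MultiIndex.from_tuples(
        calls.columns, names=["cell_line", "treatment"]
    )
    return calls


def icd_signature(
    table: ContrastTable,
    fc_min: float = 1.3,
    alpha: float = 0.05,
    inducer_rule: str = "any",
    strict_girr: bool = False,
    cell_lines: tuple[str, ...] = CELL_LINES,
) -> ICDSignature:
    """Select features specifically regulated by ICD inducers.

    For each direction d in {up, down}, a feature is selected when

    * in every cell line it is called d under the ICD inducers (at least one
      of DXR / RA_IFNa with ``inducer_rule="any"``, both with ``"all"``), and
    * no gamma-irradiation contrast excludes it (a d call with the default
      direction-specific exclusion; any call with ``strict_girr``).

    A feature qualifying for both directions (possible only under the "any"
    rule) is dropped from both branches and logged.
    """
    if inducer_rule not in ("any", "all"):
        raise ParameterError(f"inducer_rule must be 'any' or 'all', got {inducer_rule!r}")
    needed = {(line, t) for line in cell_lines for t in ("gIrr",) + ICD_TREATMENTS}
    have = set(table.contrasts)
    if not needed.issubset(have):
        raise ContrastError(
            f"contrast table is missing contrasts: {sorted(needed - have)}"
        )

    calls = _contrast_calls(
        table, fc_min, alpha, cell_lines, ("gIrr",) + ICD_TREATMENTS
    )
    combine = any if inducer_rule == "any" else all
    branches: dict[str, set[str]] = {"up": set(), "down": set()}
    for feature in table.features:
        row = calls.loc[feature]
        for d in ("up", "down"):
            icd_ok = all(
                combine(row[(line, t)] == d for t in ICD_TREATMENTS)
                for line in cell_lines
            )
            if not icd_ok:
                continue
            if strict_girr:
                girr_ok = all(row[(line, "gIrr")] == "ns" for line in cell_lines)
            else:
                girr_ok = all(row[(line, "gIrr")] != d for line in cell_lines)
            if girr_ok:
                branches[d].add(feature)

    ambiguous = branches["up"] & branches["down"]
    if ambiguous:
        log.warning(
            "features qualify for both directions and are dropped: %s",
            sorted(ambiguous),
        )
    return ICDSignature(
        up=branches["up"] - ambiguous,
        down=branches["down"] - ambiguous,
        provenance=calls,
    )


def differential_sets(
    table: ContrastTable,
    direction: str,
    fc_min: float = 1.3,
    alpha: float = 0.05,
) -> dict[str, set[str]]:
    """Per-contrast feature sets called in ``direction`` (for UpSet analysis).

    Keys are ``"<cell_line>-<treatment>"``.
    """
    if direction not in ("up", "down"):
        raise ParameterError(f"direction must be 'up' or 'down', got {direction!r}")
    lines = sorted({c[0] for c in table.contrasts})
    treatments = sorted({c[1] for c in table.contrasts})
    calls = _contrast_calls(table, fc_min, alpha, tuple(lines), tuple(treatments))
    return {
        f"{line}-{t}": set(calls.index[calls[(line, t)] == direction])
        for line in lines
        for t in treatments
    }


def upset_intersections(
    sets: dict[str, set],
) -> tuple[dict[frozenset, set], dict[str, int]]:
    """Exclusive intersections of a named family of sets.

    Returns ``(intersections, totals)`` where ``intersections`` maps each
    non-empty subfamily (as a frozenset of names) to the elements belonging
    to exactly those sets, and ``totals`` gives per-set sizes for the
    horizontal bars of an UpSet plot.  The exclusive intersections partition
    the union of the inputs.
    """
    names = list(sets)
    if len(set(names)) != len(names):
        raise ParameterError("duplicate set names")
    if not names:
        raise ParameterError("at least one named set is required")
    membership: dict[frozenset, set] = {}
    for element in set().union(*sets.values()):
        key = frozenset(n for n in names if element in sets[n])
        membership.setdefault(key, set()).add(element)
    totals = {n: len(sets[n]) for n in names}
    return membership, totals


def upset_table(sets: dict[str, set]) -> pd.DataFrame:
    """Exclusive intersections as a DataFrame sorted by size (descending)."""
    inter, _ = upset_intersections(sets)
    rows = [
        {
            "subfamily": "&".join(sorted(k)),
            "degree": len(k),
            "size": len(v),
            "members": ";".join(sorted(str(x) for x in v)),
        }
        for k, v in inter.items()
    ]
    rows.sort(key=lambda r: (-r["size"], r["subfamily"]))
    return pd.DataFrame(rows, columns=["subfamily", "degree", "size", "members"])


def plot_upset(sets: dict[str, set], path) -> None:
    """Minimal UpSet-style rendering (intersection bars + membership dots)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    inter, totals = upset_intersections(sets)
    names = sorted(sets)
    combos = sorted(inter, key=lambda k: (-len(inter[k]), sorted(k)))
    sizes = [len(inter[c]) for c in combos]

    fig, (ax_bar, ax_dot) = plt.subplots(
        2, 1, figsize=(max(4, len(combos) * 0.6), 5),
        sharex=True, height_ratios=[2, 1],
    )
    xs = range(len(combos))
    ax_bar.bar(xs, sizes, color="0.2")
    ax_bar.set_ylabel("intersection size")
    for x, combo in zip(xs, combos):
        for y, name in enumerate(names):
            inside = name in combo
            ax_dot.plot(
                x, y, "o",
                color="0.2" if inside else "0.85", markersize=6,
            )
    ax_dot.set_yticks(range(len(names)))
    ax_dot.set_yticklabels(f"{n} ({totals[n]})" for n in names)
    ax_dot.set_xticks(list(xs))
    ax_dot.set_xticklabels(["" for _ in xs])
    ax_dot.set_ylim(-0.5, len(names) - 0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def brute_force_signature(
    table: ContrastTable,
    fc_min: float = 1.3,
    alpha: float = 0.05,
    inducer_rule: str = "any",
) -> ICDSignature:
    """Independent row-by-row evaluation of the selection rule.

    Kept deliberately separate from :func:`icd_signature` (no shared call
    machinery) as a cross-check implementation.
    """
    up: set[str] = set()
    down: set[str] = set()
    for f in table.features:
        cell = {}
        for line, treatment in itertools.product(
            CELL_LINES, ("gIrr",) + ICD_TREATMENTS
        ):
            fc = table.fc(f, line, treatment)
            p = table.p(f, line, treatment)
            if fc is None or p is None or p > alpha:
                cell[(line, treatment)] = "ns"
            elif fc >= fc_min:
                cell[(line, treatment)] = "up"
            elif fc <= -fc_min:
                cell[(line, treatment)] = "down"
            else:
                cell[(line, treatment)] = "ns"
        for d, bucket in (("up", up), ("down", down)):
            per_line = []
            for line in CELL_LINES:
                hits = [cell[(line, t)] == d for t in ICD_TREATMENTS]
                per_line.append(all(hits) if inducer_rule == "all" else any(hits))
            girr_free = all(cell[(line, "gIrr")] != d for line in CELL_LINES)
            if all(per_line) and girr_free:
                bucket.add(f)
    both = up & down
    return ICDSignature(up=up - both, down=down - both)
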