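"""Binding-pocket report parsing and per-target ligandability aggregation.

Consumes the block-structured per-pocket "info" text files emitted by
geometry-based pocket detectors (one block per cavity, ``key : value``
lines), flags pockets whose ligandability score clears the conventional
cutoff, and reduces a target's pocket list to a single structural
druggability signal.
"""

from __future__ import annotations

import re
from typing import Iterable, Optional

from .records import PocketReport, PocketSimilarity

__all__ = [
    "LIGANDABILITY_CUTOFF",
    "PocketParseError",
    "best_pocket_score",
    "flag_ligandable",
    "parse_pocket_info",
    "render_pocket_info",
]

#: A pocket is considered ligandable when its score strictly exceeds this.
LIGANDABILITY_CUTOFF = 0.5

_BLOCK_RE = re.compile(r"^Pocket\s+(\d+)\s*:?\s*$")
_KV_RE = re.compile(r"^\s+(.+?)\s*:\s*(.*?)\s*$")

#: Keys (lowercased) recognized as the ligandability score line.
_SCORE_KEYS = ("druggability score", "ligandability score")
_VOLUME_KEYS = ("volume", "real volume (approximation)")
_SPHERE_KEYS = ("number of alpha spheres",)


class PocketParseError(ValueError):
    """Malformed pocket-info text; the message names the offending pocket."""


def parse_pocket_info(text: str, structure_id: str = "") -> list[PocketReport]:
    """Parse one per-structure pocket-info file into pocket reports.

    Blocks start with a ``Pocket <i> :`` header and carry indented
    ``key : value`` lines; the ligandability/druggability score line is
    required per block, unrecognized keys are ignored.  An empty input
    yields an empty list.
    """
    blocks: list[tuple[int, dict[str, str]]] = []
    current: Optional[dict[str, str]] = None
    for line in text.splitlines():
        m = _BLOCK_RE.match(line.strip()) if line.strip().startswith("Pocket") else None
        if m:
            current = {}
            blocks.append((int(m.group(1)), current))
            continue
        kv = _KV_RE.match(line)
        if kv and current is not None:
            current[kv.group(1).strip().lower()] = kv.group(2)
    reports = []
    for index, fields in blocks:
        score_raw = next(
            (fields[k] for k in _SCORE_KEYS if k in fields), None
        )
        if score_raw is None:
            raise PocketParseError(
                f"pocket {index}: missing ligandability/druggability score line"
            )
        try:
            score = float(score_raw)
        except ValueError:
            raise PocketParseError(
                f"pocket {index}: ligandability score {score_raw!r} is not a number"
            ) from None
        volume = _opt_float(fields, _VOLUME_KEYS)
        spheres = _opt_float(fields, _SPHERE_KEYS)
        reports.append(
            PocketReport(
                structure_id=structure_id,
                pocket_index=index,
                ligandability_score=score,
                volume=volume,
                alpha_sphere_count=int(spheres) if spheres is not None else None,
            )
        )
    return reports


def _opt_float(fields: dict, keys) -> Optional[float]:
    for k in keys:
        if k in fields:
            try:
                return float(fields[k])
            except ValueError:
                return None
    return None


def render_pocket_info(pockets: Iterable[PocketReport]) -> str:
    """Write pocket reports back to the info-file dialect (parse inverse)."""
    lines = []
    for p in pockets:
        lines.append(f"Pocket {p.pocket_index} :")
        lines.append(f"\tDruggability Score : \t{p.ligandability_score:g}")
        if p.alpha_sphere_count is not None:
            lines.append(f"\tNumber of Alpha Spheres : \t{p.alpha_sphere_count}")
        if p.volume is not None:
            lines.append(f"\tVolume : \t{p.volume:g}")
        lines.append("")
    return "\n".join(lines)


def flag_ligandable(pocket: PocketReport) -> bool:
    """True iff the pocket's score strictly exceeds the ligandability cutoff."""
    return pocket.ligandability_score > LIGANDABILITY_CUTOFF


def best_pocket_score(
    pockets: Iterable[PocketReport],
    similarity: Optional[PocketSimilarity] = None,
) -> float:
    """Best ligandability score over a target's pockets (0 when none).

    When the target has no own-structure pockets but carries a
    sequence-search homolog annotation, the homolog's pockets contribute
    attenuated by the sequence identity fraction — a remote structural
    surrogate should never outscore an equally good own-structure pocket.
    """
    own = max((p.ligandability_score for p in pockets), default=0.0)
    if own == 0.0 and similarity is not None and similarity.pockets:
        frac = similarity.sequence_identity / 100.0
        return frac * max(p.ligandability_score for p in similarity.pockets)
    return own
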