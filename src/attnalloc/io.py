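"""Readers and writers for profiles, AOI geometry, and run configuration.

File conventions: CSV is comma-separated UTF-8 with a mandatory header row
and "." decimal separator; files always store fractions, never
percentages (percent formatting happens only in rendered tables). Profile
and config files are YAML or JSON with the same schema.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Sequence

import yaml

from .behavior import AOI
from .profile import ValueProfile

__all__ = ["load_profile", "save_profile", "load_aois", "save_aois", "load_config", "log_stage"]

logger = logging.getLogger("attnalloc")


def _load_structured(path: str | Path) -> Any:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def load_profile(path: str | Path) -> ValueProfile:
    """Read a value profile: a YAML/JSON list of ``{label, V}`` mappings
    (order preserved), or a mapping with a ``sections`` key holding one.

    Raises with the offending section named on any out-of-range V or
    duplicate label.
    """
    raw = _load_structured(path)
    if isinstance(raw, dict) and "sections" in raw:
        raw = raw["sections"]
    if not isinstance(raw, list) or not raw:
        raise ValueError(f"{path}: expected a non-empty list of sections")
    sections = []
    for i, entry in enumerate(raw):
        if not isinstance(entry, dict) or "label" not in entry or "V" not in entry:
            raise ValueError(f"{path}: section {i} must be a mapping with 'label' and 'V'")
        v = float(entry["V"])
        if not (0.0 <= v < 1.0):
            raise ValueError(
                f"{path}: section {entry['label']!r} has V={v} outside [0, 1)"
            )
        sections.append((str(entry["label"]), v))
    return ValueProfile(sections)


def save_profile(profile: ValueProfile, path: str | Path) -> None:
    path = Path(path)
    payload = [{"label": lab, "V": float(v)} for lab, v in profile]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def load_aois(path: str | Path) -> tuple[ValueProfile, list[AOI]]:
    """Read AOI geometry: a JSON/YAML list of
    ``{label, V, x0, y0, x1, y1}``; returns the profile and rectangles in
    file order."""
    raw = _load_structured(path)
    if isinstance(raw, dict) and "aois" in raw:
        raw = raw["aois"]
    if not isinstance(raw, list) or not raw:
        raise ValueError(f"{path}: expected a non-empty list of AOIs")
    sections, rects = [], []
    for entry in raw:
        missing = {"label", "V", "x0", "y0", "x1", "y1"} - set(entry)
        if missing:
            raise ValueError(f"{path}: AOI entry missing keys {sorted(missing)}")
        sections.append((str(entry["label"]), float(entry["V"])))
        rects.append(
            AOI(
                str(entry["label"]),
                float(entry["x0"]),
                float(entry["y0"]),
                float(entry["x1"]),
                float(entry["y1"]),
            )
        )
    return ValueProfile(sections), rects


def save_aois(profile: ValueProfile, aois: Sequence[AOI], path: str | Path) -> None:
    v = dict(zip(profile.labels, profile.V.tolist()))
    payload = [
        {"label": a.label, "V": v[a.label], "x0": a.x0, "y0": a.y0, "x1": a.x1, "y1": a.y1}
        for a in aois
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def load_config(path: str | Path, allowed_keys: Sequence[str]) -> dict:
    """Read a run-configuration mapping, rejecting unknown keys."""
    raw = _load_structured(path)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    unknown = set(raw) - set(allowed_keys)
    if unknown:
        raise ValueError(f"{path}: unknown configuration keys {sorted(unknown)}")
    return raw


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


def log_stage(stage: str, *, inputs: Sequence[str | Path] = (), **params: Any) -> None:
    """One structured log line per pipeline stage: resolved parameters,
    input checksums, and package version — enough to rerun exactly."""
    from . import __version__

    checks = {str(p): _checksum(p) for p in inputs if Path(p).exists()}
    logger.info(
        "stage=%s version=%s params=%s inputs=%s",
        stage,
        __version__,
        json.dumps(params, sort_keys=True, default=str),
        json.dumps(checks, sort_keys=True),
    )
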