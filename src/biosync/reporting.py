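"""Run summaries, monthly change logs, and incoming-file archiving.

Stakeholder notification is modeled as files: each run drops a
human-readable summary plus a machine-readable key/value file into an
outbox directory (transport such as SMTP is out of scope), changes are
appended to per-pipeline monthly log files, and every incoming source
file is archived under a retention policy — kept for a year, with at
least one full-load file per calendar year preserved indefinitely for
troubleshooting.
"""

from __future__ import annotations

import datetime as _dt
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .sync_engine import RunCounters


@dataclass
class RunSummary:
    """Per-run status and counters, mirroring a stakeholder summary mail."""

    pipeline_name: str
    start_tick: int
    end_tick: int
    status: str  # success | failed
    failed_phase: Optional[str] = None
    counters: RunCounters = field(default_factory=RunCounters)
    warnings: list[str] = field(default_factory=list)
    exception_text: Optional[str] = None
    sweep_outcomes: list = field(default_factory=list)

    def __post_init__(self):
        if self.status == "failed" and not self.failed_phase:
            raise ValueError("failed runs must name the failing phase")
        if self.status == "success" and self.exception_text:
            raise ValueError("successful runs carry no exception text")


_COUNTER_LABELS = (
    ("incoming", "incoming records"),
    ("matched", "matched"),
    ("conflicts", "conflicts"),
    ("new", "new records"),
    ("inserted", "added"),
    ("updated", "updated"),
    ("unchanged", "required no updates"),
    ("deleted", "removed"),
    ("skipped", "skipped"),
)


def summarize(summary: RunSummary, out_dir=None) -> str:
    """Render a run summary as text; optionally also drop the text and a
    machine-readable JSON copy into an outbox directory.

    The text block labels every counter — how many records came in, how
    many were added, removed, updated, or required no updates — and, for
    failed runs, the failing phase and the exception text.
    """
    lines = [
        f"Pipeline: {summary.pipeline_name}",
        f"Run: ticks {summary.start_tick}..{summary.end_tick}",
        f"Status: {summary.status.upper()}",
    ]
    if summary.status == "failed":
        lines.append(f"Failed phase: {summary.failed_phase}")
        lines.append(f"Error: {summary.exception_text}")
    for attr, label in _COUNTER_LABELS:
        lines.append(f"  {label}: {getattr(summary.counters, attr)}")
    for warning in summary.warnings:
        lines.append(f"WARNING: {warning}")
    text = "\n".join(lines) + "\n"

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        stem = f"{summary.pipeline_name}_run{summary.start_tick:06d}"
        (out_dir / f"{stem}.txt").write_text(text)
        payload = {
            "pipeline_name": summary.pipeline_name,
            "start_tick": summary.start_tick,
            "end_tick": summary.end_tick,
            "status": summary.status,
            "failed_phase": summary.failed_phase,
            "counters": dict(summary.counters.__dict__),
            "warnings": list(summary.warnings),
            "exception_text": summary.exception_text,
        }
        (out_dir / f"{stem}.json").write_text(json.dumps(payload, indent=2) + "\n")
    return text


def append_changelog(
    pipeline_name: str,
    entries: Sequence[str],
    month: str,
    log_dir,
    summary: Optional[RunSummary] = None,
) -> Optional[Path]:
    """Append one run block — individual changes plus summary data — to
    the pipeline's monthly log file (``<pipeline>-<YYYY-MM>.log``).

    An unwritable log directory is reported as a warning on the summary
    rather than failing the run: logging is best-effort.
    """
    try:
        log_dir = Path(log_dir)
        log_dir.mkdir(parents=True, exist_ok=True)
        path = log_dir / f"{pipeline_name}-{month}.log"
        block = [f"== run ticks {summary.start_tick}..{summary.end_tick} =="] if summary else ["== run =="]
        block.extend(entries)
        if summary is not None:
            c = summary.counters
            block.append(
                f"summary: inserted={c.inserted} updated={c.updated}"
                f" deleted={c.deleted} unchanged={c.unchanged}"
            )
        with path.open("a") as fh:
            fh.write("\n".join(block) + "\n")
        return path
    except OSError as exc:
        if summary is not None:
            summary.warnings.append(f"changelog not written: {exc}")
        return None


@dataclass(frozen=True)
class RetentionPolicy:
    keep_days: int = 365
    keep_one_per_year: bool = True


def archive_incoming(file, pipeline_name: str, date: _dt.date, archive_root) -> Path:
    """Copy an incoming source file to
    ``archive/<pipeline>/<YYYY>/<YYYY-MM-DD>_<filename>``."""
    file = Path(file)
    if not file.exists():
        raise FileNotFoundError(file)
    dest_dir = Path(archive_root) / pipeline_name / f"{date.year:04d}"
    dest_dir.mkdir(parents=True, exist_ok=True)
    dest = dest_dir / f"{date.isoformat()}_{file.name}"
    shutil.copyfile(file, dest)
    return dest


def _archived_files(archive_root, pipeline_name: str) -> list[tuple[_dt.date, Path]]:
    root = Path(archive_root) / pipeline_name
    out = []
    for p in sorted(root.glob("*/*")):
        try:
            date = _dt.date.fromisoformat(p.name[:10])
        except ValueError:
            continue
        out.append((date, p))
    return out


def purge_archive(
    archive_root,
    pipeline_name: str,
    today: _dt.date,
    policy: RetentionPolicy = RetentionPolicy(),
) -> list[Path]:
    """Delete archived files older than the retention window, keeping the
    newest file unconditionally and, per policy, the earliest file of each
    calendar year as that year's full-load representative.  Idempotent:
    purging twice removes nothing the second time."""
    files = _archived_files(archive_root, pipeline_name)
    if not files:
        return []
    newest = max(files)[1]
    keepers = {newest}
    if policy.keep_one_per_year:
        by_year: dict[int, tuple[_dt.date, Path]] = {}
        for date, path in files:
            if date.year not in by_year or (date, path) < by_year[date.year]:
                by_year[date.year] = (date, path)
        keepers.update(path for _, path in by_year.values())
    cutoff = today - _dt.timedelta(days=policy.keep_days)
    removed = []
    for date, path in files:
        if path in keepers:
            continue
        if date < cutoff:
            path.unlink()
            removed.append(path)
    return removed
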