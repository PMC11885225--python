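"""Chain/batch execution of a parsed pipeline config.

``run_chain`` applies the config's steps in order to one session: the input
recording is loaded into a keyed :class:`DatasetState` (``raw``, ``events``,
and whatever derivatives steps add), each step is resolved by name —
custom functions first, then toolbox steps, then backend (Recording-method)
steps — and called with ``(dataset, userargs)``.  Every executed step
appends one provenance record, new keys are persisted under the session's
subdirectory, and a per-session log is written.  ``run_batch`` loops the
chain over many sessions, optionally in parallel, with failure isolation:
one failing session never disturbs the others, and the batch log records
the seed, the config, and the success/error counts.

Worker seeding: session *i* runs with seed ``seed + i`` regardless of the
worker count, so serial and parallel execution produce identical
derivatives.
"""

from __future__ import annotations

import datetime
import json
import traceback
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import preproc as pp
from .config import PipelineConfig
from .containers import Epochs, EventTable, ICADecomposition, Recording, read_recording

__all__ = [
    "DatasetState",
    "SessionRecord",
    "RunManifest",
    "StepDescriptor",
    "UnresolvedStepError",
    "TOOLBOX_STEPS",
    "BACKEND_STEPS",
    "resolve_step",
    "run_chain",
    "run_batch",
    "write_logs",
]


class DatasetState(dict):
    """Keyed collection of per-session derivatives plus provenance.

    Behaves as a plain dict for custom functions; keys starting with ``_``
    are run-time scratch (RNG, summaries) and are never persisted.
    Provenance records are (step_name, userargs, timestamp, summary); the
    timestamp is written to the session log, not to the persisted state, so
    that derivative files are byte-identical across reruns.
    """

    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        self.provenance: list[tuple[str, dict, str, str]] = []

    def add_provenance(self, step_name: str, userargs: dict, summary: str) -> None:
        stamp = datetime.datetime.now().isoformat(timespec="seconds")
        self.provenance.append((step_name, dict(userargs), stamp, summary))


@dataclass
class SessionRecord:
    """Outcome of one session's chain run; ``status == 'error'`` iff an
    error trace was captured."""

    session_id: str
    input_path: str
    output_dir: str
    status: str
    log_text: str = ""
    error_trace: str = ""

    def __post_init__(self):
        if (self.status == "error") != bool(self.error_trace):
            raise ValueError("status=error iff error_trace non-empty")


@dataclass
class RunManifest:
    """Batch-level bookkeeping: config copy, seed, timing, and per-session
    outcomes."""

    config: PipelineConfig
    seed: int
    started: str
    finished: str
    sessions: list[SessionRecord] = field(default_factory=list)

    @property
    def n_success(self) -> int:
        return sum(1 for s in self.sessions if s.status == "success")

    @property
    def n_error(self) -> int:
        return sum(1 for s in self.sessions if s.status == "error")


@dataclass
class StepDescriptor:
    name: str
    tier: str  # custom | toolbox | backend
    target: object


class UnresolvedStepError(KeyError):
    pass


# ---------------------------------------------------------------------------
# toolbox steps: f(dataset, userargs) -> dataset, logging via _summaries
# ---------------------------------------------------------------------------

def _note(dataset, text):
    dataset.setdefault("_summaries", []).append(text)


def _step_crop(dataset, userargs):
    rec = dataset["raw"]
    dataset["raw"] = rec.crop(userargs.get("tmin", 0.0), userargs.get("tmax"))
    _note(dataset, f"crop: duration {dataset['raw'].duration:.1f}s")
    return dataset


def _step_bandpass_filter(dataset, userargs):
    dataset["raw"] = pp.bandpass_filter(
        dataset["raw"], userargs["l_freq"], userargs["h_freq"]
    )
    _note(dataset, f"bandpass_filter: [{userargs['l_freq']}, {userargs['h_freq']}] Hz")
    return dataset


def _step_resample(dataset, userargs):
    new_sfreq = userargs["sfreq"]
    if "events" in dataset:
        dataset["raw"], dataset["events"] = pp.resample(
            dataset["raw"], new_sfreq, dataset["events"]
        )
    else:
        dataset["raw"] = pp.resample(dataset["raw"], new_sfreq)
    _note(dataset, f"resample: {new_sfreq} Hz")
    return dataset


def _step_bad_channels(dataset, userargs):
    dataset["raw"], summary = pp.detect_bad_channels(dataset["raw"], **userargs)
    _note(dataset, summary)
    return dataset


def _step_bad_segments(dataset, userargs):
    dataset["raw"], summary = pp.detect_bad_segments(dataset["raw"], **userargs)
    _note(dataset, summary)
    return dataset


def _step_ica_autoreject(dataset, userargs):
    args = dict(userargs)
    n_components = args.pop("n_components", 20)
    threshold = args.pop("threshold", 0.8)
    apply = args.pop("apply", True)
    seed = dataset.get("_seed", 0)
    ica = pp.fit_ica(dataset["raw"], n_components=n_components, seed=seed)
    ica, summary = pp.label_ics_by_correlation(
        ica, dataset["raw"], threshold=threshold
    )
    dataset["ica"] = ica
    if apply:
        dataset["raw"] = pp.apply_ic_rejection(dataset["raw"], ica)
        summary += f"; {len(ica.rejected)} components removed"
    _note(dataset, summary)
    return dataset


def _step_epoch(dataset, userargs):
    dataset["epochs"] = pp.epoch(
        dataset["raw"], dataset["events"],
        userargs.get("tmin", -0.1), userargs.get("tmax", 0.5),
    )
    ep = dataset["epochs"]
    _note(dataset, f"epoch: {ep.n_trials} trials kept, {ep.n_dropped} dropped")
    return dataset


TOOLBOX_STEPS = {
    "crop": _step_crop,
    "bandpass_filter": _step_bandpass_filter,
    "resample": _step_resample,
    "bad_channels": _step_bad_channels,
    "bad_segments": _step_bad_segments,
    "ica_autoreject": _step_ica_autoreject,
    "epoch": _step_epoch,
}


def _backend_method(name):
    def runner(dataset, userargs):
        rec = dataset["raw"]
        out = getattr(rec, name)(**userargs)
        if isinstance(out, Recording):
            dataset["raw"] = out
        _note(dataset, f"{name}: backend Recording method")
        return dataset

    runner.__name__ = f"backend_{name}"
    return runner


# generic passthroughs to Recording methods
BACKEND_STEPS = {name: _backend_method(name) for name in ("crop", "copy")}


def resolve_step(
    name: str,
    extra_funcs: dict | None = None,
    toolbox_registry: dict | None = None,
    backend_registry: dict | None = None,
) -> StepDescriptor:
    """Resolve a step name to a callable: custom > toolbox > backend.

    Registries default to the built-in toolbox and backend step tables; an
    unmatched name raises :class:`UnresolvedStepError` naming the step.
    """
    extra_funcs = extra_funcs or {}
    toolbox = TOOLBOX_STEPS if toolbox_registry is None else toolbox_registry
    backend = BACKEND_STEPS if backend_registry is None else backend_registry
    for tier, registry in (
        ("custom", extra_funcs), ("toolbox", toolbox), ("backend", backend)
    ):
        if name in registry:
            return StepDescriptor(name, tier, registry[name])
    raise UnresolvedStepError(
        f"step '{name}' not found in custom, toolbox, or backend registries"
    )


def _normalize_extra_funcs(extra_funcs) -> dict:
    if extra_funcs is None:
        return {}
    if isinstance(extra_funcs, dict):
        return dict(extra_funcs)
    return {f.__name__: f for f in extra_funcs}


def _load_inputs(input_path) -> DatasetState:
    dataset = DatasetState()
    if isinstance(input_path, Recording):
        dataset["raw"] = input_path.copy()
        return dataset
    path = Path(input_path)
    dataset["raw"] = read_recording(path)
    ev_path = path.with_suffix(".events.tsv")
    if ev_path.exists():
        dataset["events"] = EventTable.load(ev_path)
    return dataset


def _persist_state(dataset: DatasetState, session_dir: Path) -> list[str]:
    session_dir.mkdir(parents=True, exist_ok=True)
    saved, scalars = [], {}
    for key in sorted(dataset):
        if key.startswith("_"):
            continue
        val = dataset[key]
        if isinstance(val, EventTable):
            val.save(session_dir / f"{key}.tsv")
        elif isinstance(val, (Recording, Epochs, ICADecomposition)):
            val.save(session_dir / key)
        elif isinstance(val, np.ndarray):
            np.save(session_dir / f"{key}.npy", val)
        elif isinstance(val, (bool, int, float, str, list, dict, type(None))):
            scalars[key] = val
        else:
            scalars[key] = repr(val)
        saved.append(key)
    state = {
        "keys": saved,
        "scalars": scalars,
        "provenance": [
            {"step": s, "userargs": u, "summary": m}
            for s, u, _, m in dataset.provenance
        ],
    }
    (session_dir / "state.json").write_text(
        json.dumps(state, sort_keys=True, indent=1, default=str) + "\n"
    )
    return saved


def _now() -> str:
    return datetime.datetime.now().isoformat(timespec="seconds")


def run_chain(
    config: PipelineConfig,
    input_path,
    output_dir,
    extra_funcs=None,
    seed: int = 0,
    session_id: str | None = None,
) -> tuple[DatasetState, SessionRecord]:
    """Apply the config's steps in order to one session.

    On a step failure the traceback is captured, later steps are skipped,
    and partial outputs are retained; the caller inspects
    ``SessionRecord.status``.  The session log records the seed, every step
    with its arguments, and each step's output summary.
    """
    output_dir = Path(output_dir)
    if session_id is None:
        session_id = (
            Path(str(input_path)).name.split(".")[0]
            if not isinstance(input_path, Recording)
            else "session"
        )
    funcs = _normalize_extra_funcs(extra_funcs)
    log_lines = [
        f"[{_now()}] chain start: session={session_id}",
        f"[{_now()}] seed: {seed}",
    ]
    error_trace = ""
    dataset = DatasetState()
    try:
        dataset = _load_inputs(input_path)
        dataset["_seed"] = seed
        dataset["_rng"] = np.random.default_rng(seed)
        for step in config.steps:
            desc = resolve_step(step.name, funcs)
            n_before = len(dataset.setdefault("_summaries", []))
            dataset = desc.target(dataset, step.args)
            new = dataset.get("_summaries", [])[n_before:]
            summary = "; ".join(new) if new else "ok"
            dataset.add_provenance(step.name, step.args, summary)
            log_lines.append(
                f"[{_now()}] step {step.name} ({desc.tier}) args={step.args}: "
                f"{summary}"
            )
    except Exception:
        error_trace = traceback.format_exc()
        log_lines.append(f"[{_now()}] ERROR:\n{error_trace}")
    session_dir = output_dir / session_id
    try:
        _persist_state(dataset, session_dir)
    except Exception:
        if not error_trace:
            error_trace = traceback.format_exc()
            log_lines.append(f"[{_now()}] ERROR persisting state:\n{error_trace}")
    status = "error" if error_trace else "success"
    log_lines.append(f"[{_now()}] chain end: status={status}")
    log_text = "\n".join(log_lines) + "\n"
    log_dir = output_dir / "logs"
    log_dir.mkdir(parents=True, exist_ok=True)
    (log_dir / f"{session_id}.log").write_text(log_text)
    record = SessionRecord(
        session_id=session_id,
        input_path=str(input_path) if not isinstance(input_path, Recording)
        else "<in-memory recording>",
        output_dir=str(session_dir),
        status=status,
        log_text=log_text,
        error_trace=error_trace,
    )
    return dataset, record


def _chain_task(config, path, output_dir, funcs, seed, session_id):
    _, record = run_chain(
        config, path, output_dir, extra_funcs=funcs, seed=seed,
        session_id=session_id,
    )
    return record


def run_batch(
    config: PipelineConfig,
    input_paths,
    output_dir,
    n_workers: int = 1,
    seed: int = 0,
    extra_funcs=None,
    session_ids: list[str] | None = None,
) -> RunManifest:
    """Run the chain over many sessions with failure isolation.

    ``input_paths`` may be paths or ``(session_id, path)`` pairs as returned
    by :func:`~ephys_batch.study.find_sessions`.  Session *i* always runs
    with seed ``seed + i``, making results independent of ``n_workers``.
    """
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    output_dir = Path(output_dir)
    pairs = []
    for i, item in enumerate(input_paths):
        if isinstance(item, tuple):
            pairs.append(item)
        else:
            sid = (session_ids[i] if session_ids
                   else Path(str(item)).name.split(".")[0])
            pairs.append((sid, item))
    started = _now()
    if not pairs:
        warnings.warn("run_batch called with zero input paths")
        records = []
    elif n_workers == 1:
        records = [
            _chain_task(config, p, output_dir, extra_funcs, seed + i, sid)
            for i, (sid, p) in enumerate(pairs)
        ]
    else:
        from joblib import Parallel, delayed

        records = Parallel(n_jobs=n_workers)(
            delayed(_chain_task)(config, p, output_dir, extra_funcs, seed + i, sid)
            for i, (sid, p) in enumerate(pairs)
        )
    manifest = RunManifest(
        config=config, seed=seed, started=started, finished=_now(),
        sessions=list(records),
    )
    write_logs(manifest, output_dir)
    return manifest


def write_logs(manifest: RunManifest, output_dir) -> Path:
    """Write the batch log (timestamps, seed, config copy, success counts);
    per-session logs are written by :func:`run_chain`."""
    output_dir = Path(output_dir)
    log_dir = output_dir / "logs"
    log_dir.mkdir(parents=True, exist_ok=True)
    lines = [
        f"batch started:  {manifest.started}",
        f"batch finished: {manifest.finished}",
        f"random seed: {manifest.seed}",
        f"sessions: {len(manifest.sessions)} "
        f"({manifest.n_success} success, {manifest.n_error} error)",
        "",
        "config:",
        manifest.config.raw_text or manifest.config.render(),
        "",
    ]
    for s in manifest.sessions:
        lines.append(f"  {s.session_id}: {s.status}")
        if s.error_trace:
            lines.append("    " + s.error_trace.replace("\n", "\n    "))
    path = log_dir / "batch.log"
    path.write_text("\n".join(lines) + "\n")
    return path
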