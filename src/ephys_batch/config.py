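"""YAML pipeline-config parsing.

A config is a YAML document with an optional ``meta`` section (event-name
to integer-code map, either directly or under ``meta: event_codes:``) and a
steps section (``preproc:`` or ``steps:``) holding an ordered list of
processing steps.  Each step is either a bare name or a single-key map from
the step name to its keyword arguments::

    meta:
      event_codes: {famous: 1, unfamiliar: 2, scrambled: 3}
    preproc:
      - crop: {tmin: 10}
      - bandpass_filter: {l_freq: 1, h_freq: 45}
      - bad_segments: {window_s: 1}
      - bad_channels: {}
      - ica_autoreject: {n_components: 20}

Step order is preserved exactly as written and the same step may appear any
number of times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

__all__ = ["PipelineStep", "PipelineConfig", "ConfigError", "parse_config"]


class ConfigError(ValueError):
    """Malformed pipeline config (bad markup or bad schema)."""


@dataclass(frozen=True)
class PipelineStep:
    name: str
    userargs: tuple  # sorted (key, value) pairs, hashable

    @classmethod
    def make(cls, name: str, userargs: dict | None) -> "PipelineStep":
        args = userargs or {}
        return cls(name, tuple(sorted(args.items(), key=lambda kv: kv[0])))

    @property
    def args(self) -> dict:
        return dict(self.userargs)


@dataclass
class PipelineConfig:
    """Parsed processing recipe: event-code meta, ordered steps, and the
    verbatim source text.  Equality compares meta and steps (the source
    text may be reformatted without changing the pipeline)."""

    meta: dict = field(default_factory=dict)
    steps: list[PipelineStep] = field(default_factory=list)
    raw_text: str = ""

    def __eq__(self, other):
        if not isinstance(other, PipelineConfig):
            return NotImplemented
        return self.meta == other.meta and self.steps == other.steps

    def render(self) -> str:
        """Canonical YAML for this pipeline (parses back to an equal config)."""
        doc: dict = {}
        if self.meta:
            doc["meta"] = {"event_codes": dict(self.meta)}
        doc["preproc"] = [{s.name: s.args} for s in self.steps]
        return yaml.safe_dump(doc, sort_keys=False, default_flow_style=False)


def parse_config(text: str) -> PipelineConfig:
    """Parse YAML config text into a :class:`PipelineConfig`.

    Raises :class:`ConfigError` naming the offending line for malformed
    markup, or describing the entry for schema violations.
    """
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as err:
        mark = getattr(err, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"malformed YAML{where}: {err}") from err
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError("config must be a YAML mapping")

    meta_raw = doc.get("meta") or {}
    if not isinstance(meta_raw, dict):
        raise ConfigError("'meta' section must be a mapping")
    meta = meta_raw.get("event_codes", meta_raw)
    if not isinstance(meta, dict):
        raise ConfigError("'meta.event_codes' must be a mapping")
    for k, v in meta.items():
        if not isinstance(v, int):
            raise ConfigError(f"event code for '{k}' must be an integer, got {v!r}")

    steps_raw = doc.get("preproc", doc.get("steps"))
    if steps_raw is None:
        steps_raw = []
    if not isinstance(steps_raw, list):
        raise ConfigError("steps section must be a list")
    steps = []
    for i, entry in enumerate(steps_raw):
        if isinstance(entry, str):
            steps.append(PipelineStep.make(entry, {}))
        elif isinstance(entry, dict) and len(entry) == 1:
            (name, args), = entry.items()
            if args is None:
                args = {}
            if not isinstance(name, str) or not isinstance(args, dict):
                raise ConfigError(
                    f"step entry {i + 1} must map one step name to an "
                    f"argument mapping, got {entry!r}"
                )
            steps.append(PipelineStep.make(name, args))
        else:
            raise ConfigError(
                f"step entry {i + 1} must be a name or a single-key "
                f"name -> args map, got {entry!r}"
            )
    return PipelineConfig(meta=dict(meta), steps=steps, raw_text=text)
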