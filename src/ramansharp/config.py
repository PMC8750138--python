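"""Plain-text run configuration: one ``key = value`` pair per line.

The same text is echoed into output file headers so every result file
records how it was produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

METHODS = ("nn", "ep", "bd", "bd2", "wo", "mf", "fs")

_KNOWN_KEYS = {
    "method", "input", "output", "peaks_output", "seed",
    # method parameters
    "alpha", "lambda", "epsilon",
    "resolution", "alignment",
    "psf_size", "damping", "iterations",
    "damp_threshold",
    "max_shift", "width_max", "width_fraction",
    "height_threshold", "initial_width",
}

_FLOAT_KEYS = {
    "alpha", "lambda", "epsilon", "damping", "damp_threshold",
    "width_max", "width_fraction", "height_threshold",
}
_INT_KEYS = {"seed", "resolution", "alignment", "psf_size", "iterations",
             "max_shift", "initial_width"}


@dataclass
class RunConfig:
    """Parsed run configuration: a method name plus its parameters and paths."""

    method: str
    params: dict = field(default_factory=dict)
    input: str | None = None
    output: str | None = None
    peaks_output: str | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(
                f"unknown method {self.method!r}; expected one of {METHODS}"
            )

    def header(self) -> str:
        """Key-value echo for provenance headers."""
        lines = [f"method = {self.method}"]
        for k, v in sorted(self.params.items()):
            lines.append(f"{k} = {v}")
        if self.seed is not None:
            lines.append(f"seed = {self.seed}")
        return "\n".join(lines)


def parse_config(text: str) -> RunConfig:
    """Parse ``key = value`` lines; unknown keys are rejected."""
    pairs = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if "=" not in stripped:
            raise ValueError(f"line {lineno}: expected 'key = value'")
        key, _, value = stripped.partition("=")
        key, value = key.strip(), value.strip()
        if key not in _KNOWN_KEYS:
            raise ValueError(f"line {lineno}: unknown configuration key {key!r}")
        if key in pairs:
            raise ValueError(f"line {lineno}: duplicate key {key!r}")
        pairs[key] = value
    if "method" not in pairs:
        raise ValueError("configuration must name a method")
    method = pairs.pop("method")
    input_path = pairs.pop("input", None)
    output_path = pairs.pop("output", None)
    peaks_output = pairs.pop("peaks_output", None)
    seed = pairs.pop("seed", None)
    params = {}
    for key, value in pairs.items():
        if key in _INT_KEYS:
            params[key] = int(value)
        elif key in _FLOAT_KEYS:
            params[key] = float(value)
        else:
            params[key] = value
    return RunConfig(
        method=method,
        params=params,
        input=input_path,
        output=output_path,
        peaks_output=peaks_output,
        seed=int(seed) if seed is not None else None,
    )


def load_config(path) -> RunConfig:
    return parse_config(Path(path).read_text())
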