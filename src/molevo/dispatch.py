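"""Unified dispatch of external alignment and inference tools.

Each tool ships a :class:`ToolProfile` — executable, supported input
formats, the input-file flag, a score-parsing pattern and a dictionary of
keyword-named configurations (always including ``default``).  Profiles
are data (``data/tool_profiles.json``), not code, so users can edit or
extend them when a tool's flag inventory drifts between versions.
Callers hand the interface a tool name, an input file and either a
keyword or an explicit argument list; the dispatcher converts the input
format when the tool cannot read it, runs the executable in a scratch
directory, and parses the result (an alignment, or a tree plus its
log-likelihood score).

Tools absent from the registry can still be run by supplying their
supported-format list and input flag (the custom-tool path).
"""

from __future__ import annotations

import copy
import json
import re
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import dendropy
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment

from .errors import (
    CapabilityError,
    ToolExecutionError,
    ToolOutputError,
    ToolUnavailableError,
    UnknownKeywordError,
    ValidationError,
)

__all__ = [
    "ToolProfile",
    "get_profile",
    "register_tool",
    "registered_tools",
    "get_config",
    "run_aligner",
    "run_inference",
]

_SEQ_FORMATS = {"fasta", "genbank", "phylip", "phylip-relaxed", "clustal"}


@dataclass
class ToolProfile:
    """Everything the dispatcher needs to drive one external tool."""

    name: str
    executable: str
    task: str  # "alignment" | "tree"
    input_formats: tuple[str, ...]
    input_flag: str | None = None
    score_pattern: str | None = None
    supports_bootstrap: bool = False
    bootstrap_flag: str | None = None
    configs: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.input_formats:
            raise ValidationError(f"tool {self.name!r}: no supported input formats")
        self.input_formats = tuple(self.input_formats)
        self.configs = {k: tuple(v) for k, v in self.configs.items()}
        if "default" not in self.configs:
            raise ValidationError(f"tool {self.name!r}: missing 'default' keyword")


def _load_builtin_profiles() -> dict[str, ToolProfile]:
    text = resources.files("molevo.data").joinpath("tool_profiles.json").read_text()
    out = {}
    for name, raw in json.loads(text).items():
        out[name] = ToolProfile(
            name=name,
            executable=raw["executable"],
            task=raw["task"],
            input_formats=tuple(raw["input_formats"]),
            input_flag=raw.get("input_flag"),
            score_pattern=raw.get("score_pattern"),
            supports_bootstrap=raw.get("supports_bootstrap", False),
            bootstrap_flag=raw.get("bootstrap_flag"),
            configs={k: tuple(v) for k, v in raw["configs"].items()},
        )
    return out


_REGISTRY: dict[str, ToolProfile] = _load_builtin_profiles()


def registered_tools() -> list[str]:
    return sorted(_REGISTRY)


def get_profile(tool: str) -> ToolProfile:
    try:
        return copy.deepcopy(_REGISTRY[tool])
    except KeyError:
        raise UnknownKeywordError(tool, tool, registered_tools()) from None


def register_tool(profile: ToolProfile) -> None:
    """Add or replace a tool profile in the registry."""
    _REGISTRY[profile.name] = copy.deepcopy(profile)


def get_config(
    tool: str | ToolProfile, config: str | list[str] | tuple[str, ...] | None = None
) -> list[str]:
    """Resolve a keyword to its argument list.

    Explicit argument lists pass through untouched; ``None`` means the
    tool's ``default`` keyword.
    """
    profile = tool if isinstance(tool, ToolProfile) else get_profile(tool)
    if config is None:
        config = "default"
    if isinstance(config, (list, tuple)):
        return list(config)
    if config not in profile.configs:
        raise UnknownKeywordError(profile.name, config, list(profile.configs))
    return list(profile.configs[config])


def _custom_profile(
    name: str, task: str, input_formats, input_flag
) -> ToolProfile:
    if input_formats is None or input_flag is None:
        raise UnknownKeywordError(name, name, registered_tools())
    return ToolProfile(
        name=name,
        executable=name,
        task=task,
        input_formats=tuple(input_formats),
        input_flag=input_flag or None,
        configs={"default": ()},
    )


def _resolve_profile(tool, task, input_formats, input_flag) -> ToolProfile:
    if isinstance(tool, ToolProfile):
        return tool
    if tool in _REGISTRY:
        return get_profile(tool)
    # custom-tool path: an unregistered executable run with user-supplied
    # format list and input flag
    return _custom_profile(tool, task, input_formats, input_flag)


def _convert_input(
    input_path: str, input_format: str, profile: ToolProfile, scratch: Path
) -> str:
    if input_format in profile.input_formats:
        return input_path
    if input_format not in _SEQ_FORMATS:
        raise ValidationError(f"unknown input format {input_format!r}")
    target = profile.input_formats[0]
    if target not in _SEQ_FORMATS:
        raise ValidationError(f"unknown tool format {target!r}")
    converted = scratch / f"input.{target}"
    records = list(SeqIO.parse(input_path, input_format))
    with open(converted, "w") as handle:
        SeqIO.write(records, handle, target)
    return str(converted)


def _invoke(profile: ToolProfile, args: list[str], input_arg: str) -> subprocess.CompletedProcess:
    cmd = [profile.executable, *args]
    if profile.input_flag:
        cmd += [profile.input_flag, input_arg]
    else:
        cmd.append(input_arg)
    try:
        proc = subprocess.run(cmd, capture_output=True, text=True)
    except FileNotFoundError as exc:
        raise ToolUnavailableError(
            f"external tool {profile.executable!r} was not found on PATH; "
            f"install it or point the profile at the executable"
        ) from exc
    if proc.returncode != 0:
        raise ToolExecutionError(
            f"{profile.executable} exited with status {proc.returncode}: "
            f"{proc.stderr.strip() or proc.stdout.strip()}"
        )
    return proc


def run_aligner(
    tool: str | ToolProfile,
    input_path: str,
    input_format: str = "fasta",
    config: str | list[str] | None = None,
    output_path: str | None = None,
    output_format: str | None = None,
    *,
    input_formats=None,
    input_flag: str | None = None,
) -> MultipleSeqAlignment:
    """Run an external multiple-sequence aligner.

    The input is converted to a tool-supported format when needed (in a
    scratch directory that is removed whatever happens); the alignment is
    parsed from the tool's stdout (FASTA) and optionally also written to
    ``output_path`` in ``output_format``.
    """
    profile = _resolve_profile(tool, "alignment", input_formats, input_flag)
    args = get_config(profile, config)
    with tempfile.TemporaryDirectory(prefix="molevo-align-") as scratch:
        actual_input = _convert_input(
            input_path, input_format, profile, Path(scratch)
        )
        proc = _invoke(profile, args, actual_input)
        try:
            alignment = AlignIO.read(_string_handle(proc.stdout), "fasta")
        except ValueError as exc:
            raise ToolOutputError(
                f"{profile.name} produced no parseable FASTA alignment: {exc}"
            ) from exc
    if output_path is not None:
        with open(output_path, "w") as handle:
            AlignIO.write(alignment, handle, output_format or "fasta")
    return alignment


def run_inference(
    tool: str | ToolProfile,
    input_path: str,
    input_format: str = "fasta",
    config: str | list[str] | None = None,
    bootstraps: int | None = None,
    output_path: str | None = None,
    *,
    input_formats=None,
    input_flag: str | None = None,
    score_pattern: str | None = None,
) -> tuple[dendropy.Tree, float]:
    """Run an external phylogenetic-inference tool.

    Returns the tree (newick on stdout) together with its log-likelihood
    score, parsed with the profile's ``score_pattern`` (last match in the
    combined stdout+stderr).  Requesting bootstraps from a tool whose
    profile lacks that capability is a :class:`CapabilityError`.
    """
    profile = _resolve_profile(tool, "tree", input_formats, input_flag)
    if score_pattern is not None:
        profile.score_pattern = score_pattern
    args = get_config(profile, config)
    if bootstraps is not None:
        if not profile.supports_bootstrap or not profile.bootstrap_flag:
            raise CapabilityError(
                f"tool {profile.name!r} does not support bootstrap generation"
            )
        args += [profile.bootstrap_flag, str(bootstraps)]
    with tempfile.TemporaryDirectory(prefix="molevo-infer-") as scratch:
        actual_input = _convert_input(
            input_path, input_format, profile, Path(scratch)
        )
        proc = _invoke(profile, args, actual_input)
    try:
        tree = dendropy.Tree.get(
            data=proc.stdout, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise ToolOutputError(
            f"{profile.name} produced no parseable newick tree: {exc}"
        ) from exc
    if not profile.score_pattern:
        raise ToolOutputError(
            f"tool {profile.name!r} has no score pattern configured"
        )
    matches = re.findall(profile.score_pattern, proc.stdout + "\n" + proc.stderr)
    if not matches:
        raise ToolOutputError(
            f"no log-likelihood score matching pattern "
            f"{profile.score_pattern!r} in {profile.name} output"
        )
    score = float(matches[-1])
    if output_path is not None:
        with open(output_path, "w") as handle:
            handle.write(
                tree.as_string(
                    schema="newick", suppress_rooting=True, unquoted_underscores=True
                )
            )
    return tree, score


def _string_handle(text: str):
    import io

    return io.StringIO(text)


def tool_available(tool: str | ToolProfile) -> bool:
    """Whether the tool's executable resolves on PATH."""
    profile = tool if isinstance(tool, ToolProfile) else get_profile(tool)
    return shutil.which(profile.executable) is not None
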