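"""Exception hierarchy shared across the toolkit."""


class MolevoError(Exception):
    """Base class for all toolkit errors."""


class ParseError(MolevoError, ValueError):
    """A file or stream could not be parsed."""


class ValidationError(MolevoError, ValueError):
    """An object violates a structural invariant."""


class UnknownKeywordError(MolevoError, KeyError):
    """A configuration keyword is not registered for a tool."""

    def __init__(self, tool: str, keyword: str, available: list[str]):
        self.tool = tool
        self.keyword = keyword
        self.available = sorted(available)
        super().__init__(
            f"unknown keyword {keyword!r} for tool {tool!r}; "
            f"available keywords: {', '.join(self.available)}"
        )


class ToolUnavailableError(MolevoError, OSError):
    """The external executable could not be found (not a usage error)."""


class ToolExecutionError(MolevoError, RuntimeError):
    """The external tool exited with a non-zero status."""


class ToolOutputError(MolevoError, ValueError):
    """The external tool's output could not be parsed as promised."""


class CapabilityError(MolevoError, ValueError):
    """A requested option is unsupported by the selected tool profile."""
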