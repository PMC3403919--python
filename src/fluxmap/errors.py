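"""Typed exceptions shared across the package.

Every user-facing failure mode has its own class so that callers (and the
CLI) can distinguish template syntax problems from cross-reference problems
from numeric problems without string matching.
"""


class FluxMapError(Exception):
    """Base class for all errors raised by this package."""


# --- template / equation parsing ------------------------------------------

class MalformedEquation(FluxMapError):
    """Reaction equation text does not conform to the equation grammar."""


class DuplicateReactant(MalformedEquation):
    """The same metabolite label appears twice on one side of an equation."""


class TemplateFormatError(FluxMapError):
    """A template file is missing a section or has an unreadable layout."""


class CrossReferenceError(FluxMapError):
    """A measurement refers to an undeclared condition, timepoint or reaction."""


class MissingWeightError(FluxMapError):
    """Metabolites referenced by reactions lack a substance-weight entry."""

    def __init__(self, labels):
        self.labels = sorted(labels)
        super().__init__(
            "no substance weight declared for: " + ", ".join(self.labels)
        )


class ValidationError(FluxMapError):
    """An in-memory object violates its declared invariants."""


class IOFailure(FluxMapError):
    """A file could not be read or written."""


# --- network model ---------------------------------------------------------

class EmptyNetwork(FluxMapError):
    """An operation that needs at least one reaction received none."""


class TopologyConflict(FluxMapError):
    """An existing reaction has the same label but different topology."""


class BipartiteInferenceError(FluxMapError):
    """Node kinds could not be inferred for a kind-less network format."""


# --- mapping / validation --------------------------------------------------

class UnmappedMeasurement(FluxMapError):
    """Measurements refer to reactions absent from the network."""

    def __init__(self, names):
        self.names = sorted(names)
        super().__init__(
            "measurements for reactions not in the network: "
            + ", ".join(self.names)
        )


class NumericError(FluxMapError):
    """A numeric input was NaN or infinite."""


# --- layout / interaction --------------------------------------------------

class NoSuchLabel(FluxMapError):
    """No metabolite node carries the requested label."""


class AlreadySplit(FluxMapError):
    """split_label called on a label that already has clones."""


class NotSplit(FluxMapError):
    """unsplit_label called on a label with a single clone-0 node."""


class NothingToConnect(FluxMapError):
    """reconnect_label needs at least two clones of the label."""


class LayoutCoverageError(FluxMapError):
    """A layout does not assign coordinates to every node."""


# --- fixtures --------------------------------------------------------------

class SpecError(FluxMapError):
    """A fixture specification is infeasible (e.g. a 1-reaction cycle)."""
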