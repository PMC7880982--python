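"""Exception hierarchy.

The CLI maps these onto distinct exit codes so that batch callers can tell
"your inputs are broken" apart from "this anatomy admits no safe corridor".
"""


class PlanningError(Exception):
    """Base class for all stapplan errors."""


class InputError(PlanningError):
    """Unreadable, empty or malformed input file."""


class ConfigurationError(PlanningError):
    """Invalid planning configuration or anatomy manifest."""


class InfeasibleCaseError(PlanningError):
    """No orientation in the grid admits a drillable region."""


class CorridorError(PlanningError):
    """The corridor cannot be constructed along the chosen trajectory."""
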