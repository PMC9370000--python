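"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input violates a physical precondition (negative concentration, etc.)."""


class DegenerateScenarioError(ValueError):
    """A steady state is undefined because every sink of a species is zero.

    The message names the missing sink so the caller can fix the scenario or
    switch to a formulation that remains defined (e.g. the exact quadratic
    NO2 solution instead of the linear one when DOC = 0).
    """
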