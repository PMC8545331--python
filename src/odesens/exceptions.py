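"""Exception hierarchy for odesens."""


class OdesensError(Exception):
    """Base class for all odesens errors."""


class MalformedDocumentError(OdesensError):
    """The input document is not structurally valid XML/SBML."""


class UnsupportedFeatureError(OdesensError):
    """The document uses an SBML construct outside the supported ODE subset.

    Carries the import diagnostics so callers can list every offending
    construct, not just the first.
    """

    def __init__(self, diagnostics):
        self.diagnostics = diagnostics
        msgs = "; ".join(
            f"{c} at {loc}: {m}" for c, loc, m in diagnostics.unsupported_features
        )
        super().__init__(f"unsupported SBML feature(s): {msgs}")


class ModelValidationError(OdesensError):
    """A programmatically built model violates a structural invariant."""


class CompilationError(OdesensError):
    """Symbolic differentiation or numeric compilation failed for an expression."""


class IntegrationFailureError(OdesensError):
    """The ODE integrator failed (step-size underflow or step budget exhausted)."""

    def __init__(self, message, t_failure=None, phase=None):
        self.t_failure = t_failure
        self.phase = phase
        if t_failure is not None:
            message = f"{message} (at t={t_failure!r})"
        if phase is not None:
            message = f"[{phase}] {message}"
        super().__init__(message)


class SteadyStateFailureError(OdesensError):
    """Neither Newton nor simulation reached the weighted-RMS steady-state criterion."""

    def __init__(self, message, phase=None):
        self.phase = phase
        if phase is not None:
            message = f"[{phase}] {message}"
        super().__init__(message)


class SingularJacobianError(OdesensError):
    """The Jacobian is singular at the current point.

    For steady-state problems this typically signals conservation laws
    (rank-deficient stoichiometry)."""


class NotSupportedError(OdesensError):
    """A configuration option is recognised but intentionally not implemented."""


class PEtabFormatError(OdesensError):
    """A PEtab problem violates one or more lint rules.

    ``problems`` is the full list of violations; the message contains all of
    them so a user can fix the bundle in one pass.
    """

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__(
            "PEtab problem failed validation:\n  - " + "\n  - ".join(self.problems)
        )


class ObjectiveEvaluationError(OdesensError):
    """One or more conditions failed during an objective evaluation."""

    def __init__(self, failures):
        # failures: list of (condition_id, exception)
        self.failures = failures
        msgs = "; ".join(f"{cid}: {exc}" for cid, exc in failures)
        super().__init__(f"objective evaluation failed for condition(s): {msgs}")
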