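"""Exception types raised across the pipeline stages."""


class RDSCentralError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(RDSCentralError, ValueError):
    """Invalid configuration value (bad distribution, unknown kind, ...)."""


class OrphanRecruiterError(RDSCentralError, ValueError):
    """A recruiter id does not resolve to any respondent row."""

    def __init__(self, orphans):
        self.orphans = list(orphans)
        super().__init__(
            f"{len(self.orphans)} row(s) reference unknown recruiter ids: "
            f"{self.orphans[:10]}"
        )


class CycleError(RDSCentralError, ValueError):
    """An edge would close a cycle; recruitment trees are acyclic."""


class CrossCityError(RDSCentralError, ValueError):
    """A recruitment link crosses city boundaries; cities are analysed independently."""


class ConvergenceError(RDSCentralError, RuntimeError):
    """Power iteration failed to converge for a component."""


class EmptySelectionError(RDSCentralError, ValueError):
    """No selectable component was available for central-node selection."""
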