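"""Exception hierarchy for dgnet."""


class DGNetError(Exception):
    """Base class for all dgnet errors."""


class ConfigurationError(DGNetError):
    """Invalid population counts, connection rules, or run configuration."""


class GenerationError(DGNetError):
    """Connectivity generation failed (e.g. infeasible rule)."""


class SimulationError(DGNetError):
    """Numerical failure during network integration."""


class CalibrationError(DGNetError):
    """Single-cell calibration did not converge to its landmarks."""


class AnalysisError(DGNetError):
    """Graph-metric computation failed (e.g. disconnected graph)."""


class ParseError(DGNetError):
    """Malformed input file (edge list, spike times, adjacency)."""
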