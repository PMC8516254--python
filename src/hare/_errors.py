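"""Error taxonomy shared across the package.

``InputError`` covers malformed files, inconsistent tables and invalid
arguments (CLI exit code 1); ``NumericalError`` covers failures of the
numerical machinery such as singular covariance matrices (CLI exit code 2).
"""


class InputError(ValueError):
    """Invalid user input: bad file, bad schema, or inconsistent arguments."""


class NumericalError(ArithmeticError):
    """A numerical routine failed (singular system, non-PSD kernel, ...)."""
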