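"""Exception hierarchy for adpkit."""


class AdpError(Exception):
    """Base class for all adpkit errors."""


class SignatureError(AdpError):
    """Malformed signature declaration."""


class AlgebraError(AdpError):
    """Algebra does not satisfy its signature, or is used outside its contract."""


class GrammarError(AdpError):
    """Fatal grammar diagnostics (type errors, epsilon-cycles) or misuse."""


class EvaluationError(AdpError):
    """Candidate tree is not well-sorted, or evaluation failed structurally."""


class InputFormatError(AdpError):
    """Malformed input file (FASTA, flowgram text, score table, config)."""
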