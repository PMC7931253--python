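"""Exception hierarchy for the foodex package."""


class FoodexError(Exception):
    """Base class for all foodex-specific errors."""


class InvalidComponent(FoodexError, ValueError):
    """A proximate component or percentage is negative or otherwise unusable."""


class NegativeDifference(FoodexError, ValueError):
    """Measured components sum above 100 g, so CHO by difference would be negative."""


class MissingField(FoodexError, ValueError):
    """A required field of a record is absent."""


class ZeroNutrient(FoodexError, ValueError):
    """No finite portion of the food can yield an exchange of a zero nutrient."""


class OutOfBand(FoodexError, ValueError):
    """A portion's nutrient load exceeds the round-off band domain."""

    def __init__(self, nutrient: str, value: float, upper: float):
        self.nutrient = nutrient
        self.value = value
        self.upper = upper
        super().__init__(
            f"{nutrient} amount {value} g is above the {upper} g band ceiling; "
            "reduce the portion or use per-100 g exchanges"
        )


class UnknownCategory(FoodexError, ValueError):
    """An exchange-category token is not recognized."""


class MalformedCount(FoodexError, ValueError):
    """An exchange count is not a non-negative multiple of 0.25."""


class UnparsableServing(FoodexError, ValueError):
    """A serving-size string does not match the expected dialect."""

    def __init__(self, text: str):
        self.text = text
        super().__init__(f"cannot parse serving measure: {text!r}")


class SchemaError(FoodexError, ValueError):
    """A tabular input violates the expected CSV schema."""


class GenerationFailure(FoodexError, RuntimeError):
    """Rejection sampling could not produce a closure-consistent record."""
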