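"""Exception hierarchy for environment, population and fixture validation."""


class FoodTravelError(Exception):
    """Base class for all package errors."""


class SchemaError(FoodTravelError):
    """A GeoJSON feature or tabular record is missing a required property."""


class ConnectivityError(FoodTravelError):
    """The road network is disconnected after snapping houses and stores."""


class SnapError(FoodTravelError):
    """A house or store lies farther than the snap radius from any road node."""


class PartitionError(FoodTravelError):
    """Zone polygons are invalid or not strictly nested."""


class UnreachableError(FoodTravelError):
    """No path exists between two nodes of a validated network."""


class ConfigurationError(FoodTravelError):
    """A tract profile, recipe or group fixture is internally inconsistent."""


class PlacementError(FoodTravelError):
    """Agents cannot be placed: a tract with agents has no houses."""


class CalibrationError(FoodTravelError):
    """Group store pools cannot meet the requested zone-share targets."""


class RecipeError(FoodTravelError):
    """A synthetic-city recipe is infeasible (e.g. more stores than nodes)."""


class JoinError(FoodTravelError):
    """A trip log record does not join to a known agent or store."""


class AlignmentError(FoodTravelError):
    """Model outputs are not aligned with the Saltelli design matrix."""
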