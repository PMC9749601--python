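"""Closed code sets for the activity-based costing (ABC-Ingredients) cube.

The costing framework classifies every valued cost cell along five axes:
a standardized programme *activity*, a resource *input* category, an
implementation *stage* (start-up vs recurrent), a nutrition-sensitive
value-chain *typology* pathway, and a treatment *arm*.  The activity and
input sets below are the standardized multisectoral nutrition categories
used throughout the package; both sets are closed — coding a ledger never
invents new categories.
"""

from __future__ import annotations

from enum import Enum


class Activity(str, Enum):
    """Standardized programme activities (closed set of 15)."""

    PLANNING_MICROPLANNING = "planning_microplanning"
    PROGRAMME_INSTALLATION = "programme_installation"
    AWARENESS_RAISING = "awareness_raising"
    TRAINING = "training"
    MATERIALS_DEVELOPMENT = "materials_development"
    MANAGEMENT = "management"
    MONITORING_EVALUATION = "monitoring_evaluation"
    PROCUREMENT = "procurement"
    DISTRIBUTION_OF_INPUTS = "distribution_of_inputs"
    SITE_SUPERVISION = "site_supervision"
    HOME_VISITS_NUTRITION_GENDER = "home_visits_nutrition_gender"
    HOME_VISITS_AGRICULTURE = "home_visits_agriculture"
    COMMUNITY_EVENTS = "community_events"
    INTEGRATION_COORDINATION = "integration_coordination"
    INDIRECT_OVERHEAD = "indirect_overhead"


class InputCategory(str, Enum):
    """Standardized resource input categories (closed set of 10)."""

    PERSONNEL_HIRED = "personnel_hired"
    PERSONNEL_BENEFICIARIES = "personnel_beneficiaries"
    SUPPLIES = "supplies"
    EQUIPMENT = "equipment"
    AGRICULTURE_SUPPLIES = "agriculture_supplies"
    AGRICULTURE_EQUIPMENT = "agriculture_equipment"
    CONTRACTED_SERVICES = "contracted_services"
    FUEL_MAINTENANCE = "fuel_maintenance"
    TRAVEL_PERDIEM_ALLOWANCES = "travel_perdiem_allowances"
    OVERHEAD = "overhead"


class Stage(str, Enum):
    START_UP = "start_up"
    RECURRENT = "recurrent"


class Typology(str, Enum):
    """Nutrition-sensitive value-chain pathways."""

    SUPPLY = "supply"
    DEMAND = "demand"
    ENABLING_ENVIRONMENT = "enabling_environment"


class ComponentScope(str, Enum):
    """Which programme component a cost serves.

    Drives treatment-arm eligibility in the additive design: the nutrition
    behaviour-change component reaches arms 2-4, agricultural extension
    arms 3-4, gender sensitisation arm 4 only; platform-wide costs support
    every intervention arm.
    """

    NUTRITION = "nutrition"
    AGRICULTURE = "agriculture"
    GENDER = "gender"
    PLATFORM_WIDE = "platform_wide"


class Cadre(str, Enum):
    """Worker cadres: nutrition frontline worker (PK), field organiser (FO),
    district manager (DM), national-level staff."""

    PK = "PK"
    FO = "FO"
    DM = "DM"
    NATIONAL = "national"


class Nature(str, Enum):
    """Financial (expenditure-based) vs economic (opportunity-cost) valuation."""

    FINANCIAL = "financial"
    ECONOMIC = "economic"


#: Months of implementation covered by the analysis window (0 .. 39).
PROGRAMME_MONTHS = 40

#: Last month index of the start-up phase (months 0-5 = first six months).
START_UP_LAST_MONTH = 5

#: Intervention arms of the additive design (control arm carries no
#: incremental cost and is not represented in the cube).
ARMS = (2, 3, 4)

#: Arms eligible for costs of each component scope.
SCOPE_ARMS: dict[ComponentScope, tuple[int, ...]] = {
    ComponentScope.NUTRITION: (2, 3, 4),
    ComponentScope.PLATFORM_WIDE: (2, 3, 4),
    ComponentScope.AGRICULTURE: (3, 4),
    ComponentScope.GENDER: (4,),
}

#: One-time launch activities; only these may be classified start-up
#: (and only when incurred during the start-up months).
ONE_TIME_ACTIVITIES = frozenset(
    {
        Activity.PLANNING_MICROPLANNING,
        Activity.PROGRAMME_INSTALLATION,
        Activity.MATERIALS_DEVELOPMENT,
        Activity.TRAINING,
    }
)

#: Field-facing activities in which beneficiaries participate directly.
FIELD_ACTIVITIES = frozenset(
    {
        Activity.TRAINING,
        Activity.HOME_VISITS_NUTRITION_GENDER,
        Activity.HOME_VISITS_AGRICULTURE,
        Activity.COMMUNITY_EVENTS,
    }
)


def calendar_year(month_index: int, start_year: int = 2016, start_month: int = 10) -> int:
    """Calendar year of a programme month (month 0 = October of the start year)."""
    return start_year + (start_month - 1 + month_index) // 12
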