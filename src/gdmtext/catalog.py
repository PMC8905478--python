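"""Message catalog: categorized, language-tagged SMS templates.

The catalog holds every text the program can send, keyed by category and
language.  In-range glucose feedback rotates through four distinct
encouragements per participant (strict round-robin, so the variety users
see is deterministic and testable); the critically-low and critically-high
tiers each have exactly one reply.  Educational and motivational messages
also rotate so consecutive weeks differ.

Catalogs round-trip losslessly through :func:`load_catalog` /
:meth:`Catalog.save` as YAML, one record per template.
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path
from typing import Iterable

import yaml

__all__ = [
    "MessageCategory",
    "MessageTemplate",
    "Catalog",
    "CatalogError",
    "load_catalog",
    "ROTATING_CATEGORIES",
]


class CatalogError(ValueError):
    """Invalid catalog content or a requested template that does not exist."""


class MessageCategory(str, enum.Enum):
    WELCOME = "welcome"
    DISCLAIMER = "disclaimer"
    ONBOARDING_QUESTION = "onboarding_question"
    REMINDER = "reminder"
    FEEDBACK_IN_RANGE = "feedback_in_range"
    FEEDBACK_OUT_OF_RANGE = "feedback_out_of_range"
    FEEDBACK_CRITICAL_LOW = "feedback_critical_low"
    FEEDBACK_CRITICAL_HIGH = "feedback_critical_high"
    EDUCATIONAL = "educational"
    MOTIVATIONAL = "motivational"


#: Categories whose templates are served round-robin per participant.
ROTATING_CATEGORIES = frozenset(
    {
        MessageCategory.FEEDBACK_IN_RANGE,
        MessageCategory.EDUCATIONAL,
        MessageCategory.MOTIVATIONAL,
    }
)

#: Every category a usable catalog must provide for at least one language.
REQUIRED_CATEGORIES = frozenset(MessageCategory)

#: Required rotation-group sizes within one language: four rotating
#: in-range replies, a single reply for each critical tier.
_GROUP_SIZE_RULES: dict[MessageCategory, int] = {
    MessageCategory.FEEDBACK_IN_RANGE: 4,
    MessageCategory.FEEDBACK_CRITICAL_LOW: 1,
    MessageCategory.FEEDBACK_CRITICAL_HIGH: 1,
}


@dataclasses.dataclass(frozen=True)
class MessageTemplate:
    template_id: str
    category: MessageCategory
    language: str
    body: str
    rotation_rank: int = 0

    def __post_init__(self) -> None:
        if not self.body.strip():
            raise CatalogError(f"template {self.template_id}: empty body")
        if self.rotation_rank < 0:
            raise CatalogError(f"template {self.template_id}: negative rank")


class Catalog:
    """A validated template collection with per-participant rotation state.

    Rotation cursors live on the catalog (not on the templates) and are
    keyed by ``(participant_id, category, language)``; interleaving
    selections for one participant never perturbs another's sequence.
    """

    def __init__(self, templates: Iterable[MessageTemplate]):
        self._groups: dict[tuple[MessageCategory, str], list[MessageTemplate]] = {}
        seen: set[tuple[MessageCategory, str, int]] = set()
        for t in templates:
            key = (t.category, t.language, t.rotation_rank)
            if key in seen:
                raise CatalogError(
                    f"duplicate (category, language, rotation_rank): "
                    f"({t.category.value}, {t.language}, {t.rotation_rank})"
                )
            seen.add(key)
            self._groups.setdefault((t.category, t.language), []).append(t)
        for group in self._groups.values():
            group.sort(key=lambda t: t.rotation_rank)
        missing = [
            c.value
            for c in MessageCategory
            if not any(cat is c for cat, _ in self._groups)
        ]
        if missing:
            raise CatalogError(f"missing required categories: {sorted(missing)}")
        self._cursors: dict[tuple[str, MessageCategory, str], int] = {}

    # -- access ------------------------------------------------------------

    @property
    def templates(self) -> list[MessageTemplate]:
        return [t for g in self._groups.values() for t in g]

    def languages(self) -> set[str]:
        return {lang for _, lang in self._groups}

    def group(self, category: MessageCategory, language: str = "en") -> list[MessageTemplate]:
        return list(self._groups.get((MessageCategory(category), language), []))

    def next_message(
        self, participant_id: str, category: MessageCategory, language: str = "en"
    ) -> MessageTemplate:
        """Select the next template of a category for one participant.

        Rotating categories advance a per-participant cursor by exactly one
        (mod group size); non-rotating categories always return the
        lowest-ranked template and keep no state.
        """
        category = MessageCategory(category)
        group = self._groups.get((category, language))
        if not group:
            raise CatalogError(
                f"no {category.value!r} template for language {language!r}"
            )
        if category not in ROTATING_CATEGORIES:
            return group[0]
        key = (participant_id, category, language)
        cursor = self._cursors.get(key, 0)
        self._cursors[key] = (cursor + 1) % len(group)
        return group[cursor % len(group)]

    def next_feedback(
        self, participant_id: str, tier, language: str = "en"
    ) -> MessageTemplate:
        """Feedback template for a glucose tier (rotating only when in range)."""
        from .glucose import tier_to_category  # local import avoids a cycle

        return self.next_message(participant_id, tier_to_category(tier), language)

    # -- validation beyond construction ------------------------------------

    def validate(self) -> list[str]:
        """Return group-size problems (empty list means the catalog is valid)."""
        problems = []
        for lang in sorted(self.languages()):
            has_feedback = any(
                (cat, lang) in self._groups for cat in _GROUP_SIZE_RULES
            )
            if not has_feedback:
                continue
            for category, expected in _GROUP_SIZE_RULES.items():
                n = len(self._groups.get((category, lang), []))
                if n != expected:
                    problems.append(
                        f"{category.value}/{lang}: expected {expected} "
                        f"template(s), found {n}"
                    )
        return problems

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        records = [
            {
                "category": t.category.value,
                "language": t.language,
                "rotation_rank": t.rotation_rank,
                "body": t.body,
            }
            for t in sorted(
                self.templates, key=lambda t: (t.category.value, t.language, t.rotation_rank)
            )
        ]
        Path(path).write_text(yaml.safe_dump(records, sort_keys=False, allow_unicode=True))


def load_catalog(source: str | Path | None = None) -> Catalog:
    """Load a catalog from a YAML file, or the built-in default when omitted."""
    if source is None:
        return Catalog(_default_templates())
    raw = yaml.safe_load(Path(source).read_text())
    if not isinstance(raw, list):
        raise CatalogError("catalog file must contain a list of template records")
    templates = []
    for i, rec in enumerate(raw):
        try:
            category = MessageCategory(rec["category"])
        except (KeyError, ValueError) as exc:
            raise CatalogError(f"record {i}: bad or missing category") from exc
        language = rec.get("language", "en")
        rank = int(rec.get("rotation_rank", 0))
        templates.append(
            MessageTemplate(
                template_id=f"{category.value}-{language}-{rank}",
                category=category,
                language=language,
                body=rec.get("body", ""),
                rotation_rank=rank,
            )
        )
    return Catalog(templates)


def _default_templates() -> list[MessageTemplate]:
    """Built-in English catalog.

    The fasting reminder, the first in-range reply, the sample educational
    and motivational texts, and the welcome/disclaimer wording follow the
    deployed program; remaining bodies (the other reminders and in-range
    variants, the out-of-range and critical replies, onboarding questions)
    are program-faithful stand-ins written to the same style.
    """
    def t(category: MessageCategory, rank: int, body: str) -> MessageTemplate:
        return MessageTemplate(
            template_id=f"{category.value}-en-{rank}",
            category=category,
            language="en",
            body=body,
            rotation_rank=rank,
        )

    C = MessageCategory
    return [
        t(C.WELCOME, 0,
          "Welcome to Text 4 Success! You will receive reminders & info about "
          "gestational diabetes. Reply STOP at any time to stop receiving messages."),
        t(C.DISCLAIMER, 0,
          "Please note: this account is not monitored by a clinician in real "
          "time. Contact your care team with any clinical questions."),
        t(C.ONBOARDING_QUESTION, 0,
          "To time your reminders, what time do you usually eat breakfast? "
          "Please reply with a time like 8:00."),
        t(C.ONBOARDING_QUESTION, 1,
          "Thank you! What time do you usually eat lunch? "
          "Please reply with a time like 12:30."),
        t(C.ONBOARDING_QUESTION, 2,
          "Almost done! What time do you usually eat dinner? "
          "Please reply with a time like 18:30."),
        t(C.REMINDER, 0,
          "Hello! This is a Text 4 Success reminder to check your number "
          "before eating your first meal. Please reply with your number only."),
        t(C.REMINDER, 1,
          "Hello! This is a Text 4 Success reminder to check your number "
          "1 hour after breakfast. Please reply with your number only."),
        t(C.REMINDER, 2,
          "Hello! This is a Text 4 Success reminder to check your number "
          "1 hour after lunch. Please reply with your number only."),
        t(C.REMINDER, 3,
          "Hello! This is a Text 4 Success reminder to check your number "
          "1 hour after dinner. Please reply with your number only."),
        t(C.FEEDBACK_IN_RANGE, 0,
          "Keep up the great work checking your numbers and taking charge "
          "of your health!"),
        t(C.FEEDBACK_IN_RANGE, 1,
          "Great job! Your number is in your goal range. Keep it up!"),
        t(C.FEEDBACK_IN_RANGE, 2,
          "Nice work — that number is right where it should be. "
          "Thanks for checking!"),
        t(C.FEEDBACK_IN_RANGE, 3,
          "Thank you for sending your number. It is in range — "
          "keep up the good work!"),
        t(C.FEEDBACK_OUT_OF_RANGE, 0,
          "Thank you for checking your number. This value is outside your "
          "goal range. Please contact your care team to discuss it."),
        t(C.FEEDBACK_CRITICAL_LOW, 0,
          "Your number is low. Please treat your low blood sugar now and "
          "contact your care team."),
        t(C.FEEDBACK_CRITICAL_HIGH, 0,
          "Your number is high. Please contact your care team."),
        t(C.EDUCATIONAL, 0,
          "Eating nutritious foods is a key part of staying healthy. One "
          "healthy snack is a plain Greek yogurt. Click for a list of more "
          "snacks: http://tinyurl.com/y2az4zn6"),
        t(C.EDUCATIONAL, 1,
          "Drinking water, instead of soda or juice, is healthy for you and "
          "can help regulate your numbers."),
        t(C.MOTIVATIONAL, 0,
          "If you feel off track, know that every day is another chance to "
          "get back on track!"),
        t(C.MOTIVATIONAL, 1,
          "You've got what it takes to keep checking your numbers!"),
    ]
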