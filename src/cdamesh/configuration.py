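"""Identification configuration: relevant sections, branches, qualifiers.

The identification run is driven by an ordered list of section rules.  A
rule matches a document section by LOINC/SNOMED code or by (normalized)
title; a matched rule supplies the MeSH tree branches and qualifier
subheadings to use there.  Two distinct defaults exist:

* the *shipped* rules associate branches A–G (the configuration with the
  best precision/recall balance);
* a rule whose branches are left unset falls back to the nine branches
  A–G, N (Health Care) and Z (Geographic Locations), the branches holding
  the most popular indexing keywords.

The disease anchoring every query is drawn from branch C (Diseases) by
default.  Configurations round-trip through a small XML schema::

    <config default-branches="ABCDEFGNZ" disease-branch="C">
      <section>
        <title>Allergies</title>
        <code system="LOINC">48765-2</code>
        <branches>CD</branches>
        <qualifiers>EP|DI</qualifiers>
      </section>
    </config>
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Optional

from lxml import etree

from .cda_reader import CdaSection, SectionCode
from .mesh_model import (
    BRANCH_LETTERS,
    MeshThesaurus,
    Qualifier,
    normalize_term,
)

__all__ = [
    "SectionRule",
    "AppConfig",
    "ConfigError",
    "DEFAULT_UNSET_BRANCHES",
    "SHIPPED_RULE_BRANCHES",
    "load_config",
    "save_config",
    "default_config",
    "resolve_section",
    "effective_branches",
    "effective_qualifiers",
]

#: Fallback for rules that leave branches unset: nine of the sixteen branches.
DEFAULT_UNSET_BRANCHES: frozenset[str] = frozenset("ABCDEFGNZ")
#: Branches carried by every shipped rule (best P/R balance).
SHIPPED_RULE_BRANCHES: frozenset[str] = frozenset("ABCDEFG")


class ConfigError(Exception):
    pass


@dataclass(frozen=True)
class SectionRule:
    """Matches document sections and scopes identification there.

    ``titles`` holds the title plus synonym titles; empty ``branches`` or
    ``qualifiers`` mean *unset* and resolve through
    :func:`effective_branches` / :func:`effective_qualifiers`.
    Qualifiers are stored as subheading abbreviations (e.g. ``EP``).
    """

    titles: frozenset[str] = frozenset()
    codes: frozenset[SectionCode] = frozenset()
    branches: frozenset[str] = frozenset()
    qualifiers: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.titles and not self.codes:
            raise ConfigError("a section rule needs at least one title or code")
        bad = self.branches - BRANCH_LETTERS
        if bad:
            raise ConfigError(f"invalid branch letter(s) in rule: {sorted(bad)}")


@dataclass(frozen=True)
class AppConfig:
    rules: tuple[SectionRule, ...]
    default_branches_when_unset: frozenset[str] = DEFAULT_UNSET_BRANCHES
    disease_branch: str = "C"

    def __post_init__(self) -> None:
        bad = self.default_branches_when_unset - BRANCH_LETTERS
        if bad:
            raise ConfigError(f"invalid default branch letter(s): {sorted(bad)}")
        if self.disease_branch not in BRANCH_LETTERS:
            raise ConfigError(f"invalid disease branch {self.disease_branch!r}")


def default_config() -> AppConfig:
    """The shipped configuration: common narrative sections, branches A–G."""
    def rule(titles: Iterable[str], loinc: str | None = None) -> SectionRule:
        codes = (
            frozenset({SectionCode(system="LOINC", code=loinc)})
            if loinc
            else frozenset()
        )
        return SectionRule(
            titles=frozenset(titles), codes=codes, branches=SHIPPED_RULE_BRANCHES
        )

    return AppConfig(
        rules=(
            rule(
                ["History of Present Illness", "Present Illness"], loinc="10164-2"
            ),
            rule(
                ["Allergies", "Allergies and Adverse Reactions"], loinc="48765-2"
            ),
            rule(["Family History", "Family Diseases"], loinc="10157-6"),
            rule(["Medications", "Current Medications"], loinc="10160-0"),
            rule(["Problems", "Problem List"], loinc="11450-4"),
            rule(["Past Medical History"], loinc="11348-0"),
        )
    )


def resolve_section(section: CdaSection, config: AppConfig) -> Optional[SectionRule]:
    """First rule matching the section; code match beats title match.

    Pass 1 scans rules in order for a shared LOINC/SNOMED code; pass 2 for
    a normalized-title match.  ``None`` means the section is irrelevant and
    is skipped by identification.
    """
    for rule in config.rules:
        if rule.codes & section.codes:
            return rule
    sec_title = normalize_term(section.title)
    if sec_title:
        for rule in config.rules:
            if sec_title in {normalize_term(t) for t in rule.titles}:
                return rule
    return None


def effective_branches(rule: SectionRule, config: AppConfig) -> frozenset[str]:
    """The rule's branches, or the nine-branch default when unset."""
    return rule.branches if rule.branches else config.default_branches_when_unset


def effective_qualifiers(
    rule: SectionRule, thesaurus: MeshThesaurus
) -> frozenset[Qualifier]:
    """The rule's qualifiers resolved against the thesaurus inventory;
    all qualifiers when the rule leaves them unset."""
    inventory = thesaurus.qualifier_inventory
    if not rule.qualifiers:
        return inventory
    return frozenset(q for q in inventory if q.abbreviation in rule.qualifiers)


# ---------------------------------------------------------------------------
# XML round-trip
# ---------------------------------------------------------------------------

def save_config(config: AppConfig, dest: str | Path | IO | None = None) -> bytes:
    root = etree.Element("config")
    root.set("default-branches", "".join(sorted(config.default_branches_when_unset)))
    root.set("disease-branch", config.disease_branch)
    for rule in config.rules:
        sec = etree.SubElement(root, "section")
        for title in sorted(rule.titles):
            etree.SubElement(sec, "title").text = title
        for code in sorted(rule.codes):
            el = etree.SubElement(sec, "code")
            el.set("system", code.system)
            el.text = code.code
        if rule.branches:
            etree.SubElement(sec, "branches").text = "".join(sorted(rule.branches))
        if rule.qualifiers:
            etree.SubElement(sec, "qualifiers").text = "|".join(sorted(rule.qualifiers))
    blob = etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)
    if dest is not None:
        if hasattr(dest, "write"):
            dest.write(blob)  # type: ignore[union-attr]
        else:
            Path(dest).write_bytes(blob)
    return blob


def load_config(xml: str | Path | bytes | IO) -> AppConfig:
    try:
        if isinstance(xml, bytes):
            root = etree.fromstring(xml)
        elif hasattr(xml, "read"):
            root = etree.parse(xml).getroot()
        else:
            root = etree.parse(str(xml)).getroot()
    except etree.XMLSyntaxError as exc:
        raise ConfigError(f"malformed config XML: {exc}") from exc

    rules: list[SectionRule] = []
    for idx, sec in enumerate(root.findall("section")):
        titles = frozenset(t.text for t in sec.findall("title") if t.text)
        codes: set[SectionCode] = set()
        for el in sec.findall("code"):
            if el.text:
                codes.add(SectionCode(system=el.get("system", "LOINC"), code=el.text))
        branches = frozenset(sec.findtext("branches") or "")
        qualifiers = frozenset(
            q for q in (sec.findtext("qualifiers") or "").split("|") if q
        )
        try:
            rules.append(
                SectionRule(
                    titles=titles,
                    codes=frozenset(codes),
                    branches=branches,
                    qualifiers=qualifiers,
                )
            )
        except ConfigError as exc:
            raise ConfigError(f"rule {idx}: {exc}") from exc
    return AppConfig(
        rules=tuple(rules),
        default_branches_when_unset=frozenset(
            root.get("default-branches", "".join(sorted(DEFAULT_UNSET_BRANCHES)))
        ),
        disease_branch=root.get("disease-branch", "C"),
    )
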