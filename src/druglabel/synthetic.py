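"""Synthetic corpus generation for offline, fully-auditable pipeline tests.

Real drug-labeling corpora are dated snapshots behind network services; this
module emulates all four source formats — SPL-style XML, free-text labels,
a DrugBank-style datafile and an Orange Book-style products file — from a
seeded template process, and records every planted fact in a ground-truth
manifest so parsers can be checked by exact round-trip.

Food-effect paragraphs come from a template set whose two *adversarial*
archetypes mirror the classic failure modes of keyword rules: a negative
that mentions "effect of food ... has not been evaluated" (rule false
positive) and a positive describing a high-fat-meal interaction without the
word "food" (rule false negative). Non-adversarial templates are, by
construction, exactly rule-separable; adversarial templates are exactly the
paragraphs where both keyword rules err. Generation is template-based, not
statistical: ground truth must be exact.
"""

from __future__ import annotations

import json
import random
import uuid
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Optional, Sequence

from lxml import etree

from .core import (
    ADMEF_SECTIONS,
    AppNumber,
    LabelDocument,
    LabeledParagraph,
    SectionKind,
    SourceName,
    normalize_text,
)

HL7_NS = "urn:hl7-org:v3"
DRUGBANK_NS = "http://www.drugbank.ca"

#: LOINC codes emitted for the eight coded SPL sections (code, display name).
_SPL_LOINC = {
    SectionKind.boxed_warning: ("34066-1", "BOXED WARNING SECTION"),
    SectionKind.indication: ("34067-9", "INDICATIONS AND USAGE SECTION"),
    SectionKind.dosage_admin: ("34068-7", "DOSAGE AND ADMINISTRATION SECTION"),
    SectionKind.pregnancy: ("42228-7", "PREGNANCY SECTION"),
    SectionKind.lactation: ("77290-5", "LACTATION SECTION"),
    SectionKind.mechanism_of_action: ("43679-0", "MECHANISM OF ACTION SECTION"),
    SectionKind.pharmacodynamics: ("43681-6", "PHARMACODYNAMICS SECTION"),
    SectionKind.pharmacokinetics: ("43682-4", "PHARMACOKINETICS SECTION"),
}

_DRUGBANK_TAGS = {
    SectionKind.indication: "indication",
    SectionKind.mechanism_of_action: "mechanism-of-action",
    SectionKind.pharmacodynamics: "pharmacodynamics",
    SectionKind.absorption: "absorption",
    SectionKind.distribution: "volume-of-distribution",
    SectionKind.metabolism: "metabolism",
    SectionKind.excretion: "route-of-elimination",
}

_FREETEXT_HEADINGS = {
    SectionKind.boxed_warning: "Boxed Warning",
    SectionKind.indication: "Indications and Usage",
    SectionKind.dosage_admin: "Dosage and Administration",
    SectionKind.pregnancy: "Pregnancy",
    SectionKind.lactation: "Lactation",
    SectionKind.mechanism_of_action: "Mechanism of Action",
    SectionKind.pharmacodynamics: "Pharmacodynamics",
    SectionKind.pharmacokinetics: "Pharmacokinetics",
}


@dataclass
class CorpusSpec:
    """Study conditions for one synthetic corpus (seed is mandatory)."""

    n_drugs: int = 20
    seed: int = 0
    #: probability that a given section is present in a given document
    p_section: float = 0.8
    #: probability that a drug appears in each labeling source
    p_in_source: dict[str, float] = field(
        default_factory=lambda: {"dailymed": 0.9, "drugs_at_fda": 0.85, "drugbank": 0.8}
    )
    p_multi_app: float = 0.15
    p_unmapped: float = 0.08
    p_multi_version: float = 0.2
    p_outside_reference: float = 0.1
    n_versions: int = 3
    #: free-text PDF-conversion noise rate (per line)
    heading_noise: float = 0.0

    def to_dict(self) -> dict:
        return {
            "n_drugs": self.n_drugs,
            "seed": self.seed,
            "p_section": self.p_section,
            "p_in_source": dict(self.p_in_source),
            "p_multi_app": self.p_multi_app,
            "p_unmapped": self.p_unmapped,
            "p_multi_version": self.p_multi_version,
            "p_outside_reference": self.p_outside_reference,
            "n_versions": self.n_versions,
            "heading_noise": self.heading_noise,
        }


# --- Paragraph templates ------------------------------------------------------


@dataclass(frozen=True)
class ParagraphTemplate:
    template: str
    label: str  # ground truth
    adversarial: bool  # True iff keyword rules 1 and 2 disagree with the label


#: Food-effect paragraphs that keyword rules catch (phrase + "food" present).
POS_TEMPLATES = (
    ParagraphTemplate(
        "When {drug} was administered with a high-fat meal, the Cmax decreased by "
        "{x}% and the AUC by {y}%; this food effect was considered clinically relevant.",
        "food_effect",
        False,
    ),
    ParagraphTemplate(
        "Administration of {drug} with a standard meal delayed the median Tmax from "
        "{t} to {t2} hours, and the effect of food on overall exposure was modest.",
        "food_effect",
        False,
    ),
    ParagraphTemplate(
        "A food effect study showed that a high-calorie breakfast increased the AUC "
        "of {drug} by approximately {x}% and the Cmax by {y}%.",
        "food_effect",
        False,
    ),
    ParagraphTemplate(
        "The effects of food on the absorption of {drug} were evaluated in {n} "
        "healthy subjects; a standard meal reduced Cmax by {x}%.",
        "food_effect",
        False,
    ),
)

#: Food-effect paragraphs without the keyword "food" — rule false negatives.
POS_ADVERSARIAL_TEMPLATES = (
    ParagraphTemplate(
        "A high-fat meal increased the extent and rate of {drug} absorption. The "
        "Cmax and AUC were increased by approximately {x} and {y}%, respectively.",
        "food_effect",
        True,
    ),
    ParagraphTemplate(
        "Following a high-calorie breakfast, the AUC of {drug} increased by {x}% "
        "and the median Tmax was delayed by {t} hours.",
        "food_effect",
        True,
    ),
    ParagraphTemplate(
        "Dosing after a standard meal reduced the Cmax of {drug} by approximately "
        "{x}% relative to the fasted state.",
        "food_effect",
        True,
    ),
)

#: Ordinary absorption paragraphs, no food vocabulary at all.
NEG_TEMPLATES = (
    ParagraphTemplate(
        "The absolute oral bioavailability of {drug} is approximately {x}%.",
        "non_food_effect",
        False,
    ),
    ParagraphTemplate(
        "Peak plasma concentrations of {drug} are reached {t} hours after oral dosing.",
        "non_food_effect",
        False,
    ),
    ParagraphTemplate(
        "{drug} is rapidly absorbed from the gastrointestinal tract, with "
        "dose-proportional exposure over the range of {d1} to {d2} mg.",
        "non_food_effect",
        False,
    ),
    ParagraphTemplate(
        "Steady-state concentrations of {drug} are achieved within {t} days of "
        "once-daily dosing.",
        "non_food_effect",
        False,
    ),
)

#: Non-food-effect paragraphs that mention a food-effect phrase — rule false positives.
NEG_ADVERSARIAL_TEMPLATES = (
    ParagraphTemplate(
        "Effect of food on the bioavailability of {drug} has not been evaluated.",
        "non_food_effect",
        True,
    ),
    ParagraphTemplate(
        "The effects of food on the pharmacokinetics of {drug} have not been "
        "studied in pediatric patients.",
        "non_food_effect",
        True,
    ),
    ParagraphTemplate(
        "A dedicated food effect study has not been conducted with {drug}.",
        "non_food_effect",
        True,
    ),
)


@dataclass
class ParagraphTemplateSet:
    positives: tuple[ParagraphTemplate, ...] = POS_TEMPLATES
    positives_adversarial: tuple[ParagraphTemplate, ...] = POS_ADVERSARIAL_TEMPLATES
    negatives: tuple[ParagraphTemplate, ...] = NEG_TEMPLATES
    negatives_adversarial: tuple[ParagraphTemplate, ...] = NEG_ADVERSARIAL_TEMPLATES


_CONSONANTS = "bdfglmnprstvz"
_VOWELS = "aeiou"
_CONDITIONS = (
    "major depressive disorder",
    "partial-onset seizures",
    "chronic heart failure",
    "moderate to severe plaque psoriasis",
    "type 2 diabetes mellitus",
    "pulmonary arterial hypertension",
)
_TARGETS = ("janus kinase 1", "factor Xa", "the serotonin transporter", "PCSK9", "SGLT2")
_MARKERS = ("blood pressure", "fasting plasma glucose", "LDL cholesterol", "heart rate")
_EVENTS = ("hepatotoxicity", "QT prolongation", "severe neutropenia", "anaphylaxis")


def _drug_name(rng: random.Random) -> str:
    n = rng.choice((3, 4))
    name = "".join(rng.choice(_CONSONANTS) + rng.choice(_VOWELS) for _ in range(n))
    if rng.random() < 0.5:
        name += rng.choice("lnrxst")
    return name.capitalize()


def fill_template(tpl: ParagraphTemplate, drug: str, rng: random.Random) -> str:
    t = rng.randrange(1, 5)
    return tpl.template.format(
        drug=drug,
        x=rng.randrange(10, 80),
        y=rng.randrange(10, 80),
        t=t,
        t2=t + rng.randrange(1, 4),
        n=rng.randrange(12, 48),
        d1=5 * rng.randrange(1, 5),
        d2=5 * rng.randrange(6, 20),
    )


@dataclass
class GeneratedParagraph:
    paragraph: LabeledParagraph
    adversarial: bool


def generate_foodeffect_paragraphs(
    n_pos: int,
    n_neg: int,
    adversarial_fraction: float,
    seed: int,
    source: SourceName = SourceName.dailymed,
    templates: Optional[ParagraphTemplateSet] = None,
) -> list[GeneratedParagraph]:
    """Labeled food-effect / non-food-effect paragraphs with lexical variation.

    ``adversarial_fraction`` of each class is drawn from the adversarial
    templates; the flag on each record marks exactly the paragraphs where
    rule-based labeling disagrees with ground truth. Deterministic given
    ``seed``.
    """
    if not 0 <= adversarial_fraction <= 1:
        raise ValueError("adversarial_fraction must lie in [0, 1]")
    tset = templates or ParagraphTemplateSet()
    rng = random.Random(f"{seed}:foodeffect")
    out: list[GeneratedParagraph] = []
    plan = (
        (n_pos, tset.positives, tset.positives_adversarial, "food_effect"),
        (n_neg, tset.negatives, tset.negatives_adversarial, "non_food_effect"),
    )
    for n, plain, adv, label in plan:
        n_adv = round(adversarial_fraction * n)
        for i in range(n):
            adversarial = i < n_adv
            tpl = rng.choice(adv if adversarial else plain)
            text = normalize_text(fill_template(tpl, _drug_name(rng), rng))
            out.append(
                GeneratedParagraph(
                    LabeledParagraph(
                        text=text,
                        label=label,
                        source=source,
                        doc_ref=f"synthetic-{label}-{i}",
                        annotation_method="manual",
                    ),
                    adversarial,
                )
            )
    rng.shuffle(out)
    return out


def generate_absorption_documents(
    n_docs: int,
    paragraphs_per_doc: int,
    adversarial_fraction: float,
    seed: int,
    source: SourceName = SourceName.dailymed,
) -> list[tuple[LabelDocument, list[GeneratedParagraph]]]:
    """Documents with planted absorption sections for annotation testing.

    Non-adversarial food-effect paragraphs are embedded under an explicit
    food-effect title line or ``Food Effect:`` prefix (the structure the regex
    annotator keys on); adversarial positives are embedded with no marker, so
    structural annotation must miss exactly those. Negatives are plain.
    """
    rng = random.Random(f"{seed}:absdocs")
    records = generate_foodeffect_paragraphs(
        n_pos=(n_docs * paragraphs_per_doc) // 2,
        n_neg=n_docs * paragraphs_per_doc - (n_docs * paragraphs_per_doc) // 2,
        adversarial_fraction=adversarial_fraction,
        seed=seed,
        source=source,
    )
    docs: list[tuple[LabelDocument, list[GeneratedParagraph]]] = []
    idx = 0
    for d in range(n_docs):
        chunk = records[idx : idx + paragraphs_per_doc]
        idx += paragraphs_per_doc
        if not chunk:
            break
        blocks: list[str] = []
        expected: list[GeneratedParagraph] = []
        for rec in chunk:
            p = rec.paragraph
            if p.label == "food_effect" and not rec.adversarial:
                phrase = rng.choice(("Food Effect", "Effect of Food", "Food Effects"))
                if rng.random() < 0.5:
                    blocks.append(phrase)  # standalone title paragraph
                    blocks.append(p.text)
                else:
                    blocks.append(f"{phrase}: {p.text}")
            else:
                blocks.append(p.text)
            expected.append(rec)
        doc = LabelDocument(
            source=source,
            native_id=f"absdoc-{d}",
            sections={SectionKind.absorption: normalize_text("\n\n".join(blocks))},
        )
        docs.append((doc, expected))
    return docs


# --- Drug universe ------------------------------------------------------------


@dataclass
class SyntheticDrug:
    name: str
    app_numbers: list[str]
    set_id: str
    drugbank_id: str
    in_reference: bool
    unmapped: bool
    n_versions: int
    sources: list[str]
    base_date: date


def make_drugs(spec: CorpusSpec) -> list[SyntheticDrug]:
    """Derive the deterministic drug universe shared by all four generators."""
    rng = random.Random(f"{spec.seed}:drugs")
    drugs: list[SyntheticDrug] = []
    next_app = 200001
    for i in range(spec.n_drugs):
        n_apps = 2 if (i == 0 or rng.random() < spec.p_multi_app) else 1
        apps = [f"{next_app + j:06d}" for j in range(n_apps)]
        next_app += n_apps
        sources = [
            s for s, p in sorted(spec.p_in_source.items()) if rng.random() < p
        ]
        if i == 0:
            sources = ["dailymed", "drugs_at_fda", "drugbank"]
        unmapped = i == 1 or (i > 3 and rng.random() < spec.p_unmapped)
        in_reference = not (i == 3 or (i > 3 and rng.random() < spec.p_outside_reference))
        n_versions = spec.n_versions if (i == 2 or rng.random() < spec.p_multi_version) else 1
        drugs.append(
            SyntheticDrug(
                name=_drug_name(rng),
                app_numbers=apps,
                set_id=str(uuid.UUID(int=rng.getrandbits(128), version=4)),
                drugbank_id=f"DB{10000 + i:05d}",
                in_reference=in_reference,
                unmapped=unmapped,
                n_versions=n_versions,
                sources=sources,
                base_date=date(2019, 1, 1) + timedelta(days=rng.randrange(0, 500)),
            )
        )
    return drugs


_SECTION_SENTENCES = {
    SectionKind.boxed_warning: "Serious {ae} has been reported in patients treated with {drug}. Monitor patients closely during the first weeks of therapy.",
    SectionKind.indication: "{drug} is indicated for the treatment of {cond} in adult patients.",
    SectionKind.dosage_admin: "The recommended starting dose of {drug} is {d} mg administered orally once daily.",
    SectionKind.pregnancy: "Available data on the use of {drug} in pregnant women are insufficient to establish a drug-associated risk of major birth defects.",
    SectionKind.lactation: "There are no data on the presence of {drug} or its metabolites in human milk.",
    SectionKind.mechanism_of_action: "{drug} is a selective inhibitor of {target}.",
    SectionKind.pharmacodynamics: "{drug} produced dose-dependent reductions in {marker} over the dosing interval.",
    SectionKind.distribution: "The apparent volume of distribution of {drug} is {v} L, indicating extensive tissue uptake.",
    SectionKind.metabolism: "{drug} is primarily metabolized by CYP{iso} to pharmacologically inactive metabolites.",
    SectionKind.excretion: "Following a single oral dose, {x}% of administered {drug} is recovered in urine and {y}% in feces.",
}

_PK_PREAMBLE = "The pharmacokinetics of {drug} are approximately linear over the therapeutic dose range."


def _section_text(kind: SectionKind, drug: SyntheticDrug, rng: random.Random) -> str:
    if kind is SectionKind.absorption:
        tpl = rng.choice(NEG_TEMPLATES)
        return fill_template(tpl, drug.name, rng)
    if kind is SectionKind.food_effect:
        tpl = rng.choice(POS_TEMPLATES)
        return fill_template(tpl, drug.name, rng)
    sent = _SECTION_SENTENCES[kind]
    return sent.format(
        drug=drug.name,
        ae=rng.choice(_EVENTS),
        cond=rng.choice(_CONDITIONS),
        target=rng.choice(_TARGETS),
        marker=rng.choice(_MARKERS),
        d=5 * rng.randrange(1, 20),
        v=rng.randrange(20, 900),
        iso=rng.choice(("3A4", "2D6", "2C9", "1A2")),
        x=rng.randrange(10, 70),
        y=rng.randrange(5, 40),
    )


def _choose_sections(
    drug: SyntheticDrug,
    rng: random.Random,
    kinds: Sequence[SectionKind],
    p: float,
    force_some: bool = True,
) -> dict[SectionKind, str]:
    chosen = [k for k in kinds if rng.random() < p]
    if force_some and not chosen:
        chosen = [SectionKind.indication if SectionKind.indication in kinds else kinds[0]]
    return {k: normalize_text(_section_text(k, drug, rng)) for k in chosen}


def _pk_block(
    sections: dict[SectionKind, str],
    preamble: str,
    rng: random.Random,
    allow_outline: bool = False,
) -> tuple[str, dict[SectionKind, str]]:
    """Assemble pharmacokinetics text with subtitle markers; return (text, expected)."""
    subs = {k: v for k, v in sections.items() if k in ADMEF_SECTIONS}
    parts: list[str] = []
    expected: dict[SectionKind, str] = {}
    if preamble:
        parts.append(preamble)
    for kind in ADMEF_SECTIONS:
        if kind not in subs:
            continue
        title = {
            SectionKind.absorption: "Absorption",
            SectionKind.distribution: "Distribution",
            SectionKind.metabolism: "Metabolism",
            SectionKind.excretion: "Excretion",
            SectionKind.food_effect: rng.choice(("Food Effect", "Effect of Food")),
        }[kind]
        if rng.random() < 0.5:
            parts.append(title)
            parts.append(subs[kind])
        else:
            parts.append(f"{title}: {subs[kind]}")
        expected[kind] = subs[kind]
    expected[SectionKind.pharmacokinetics] = preamble
    return "\n\n".join(parts), expected


# --- SPL corpus ---------------------------------------------------------------


def _spl_xml(
    drug: SyntheticDrug,
    version: int,
    eff_date: date,
    sections: dict[SectionKind, str],
    pk_text: Optional[str],
) -> bytes:
    root = etree.Element(f"{{{HL7_NS}}}document", nsmap={None: HL7_NS})
    etree.SubElement(root, f"{{{HL7_NS}}}id", root=str(uuid.uuid5(uuid.NAMESPACE_URL, f"{drug.set_id}:{version}")))
    etree.SubElement(root, f"{{{HL7_NS}}}setId", root=drug.set_id)
    etree.SubElement(root, f"{{{HL7_NS}}}versionNumber", value=str(version))
    etree.SubElement(root, f"{{{HL7_NS}}}effectiveTime", value=eff_date.strftime("%Y%m%d"))
    if not drug.unmapped:
        subject_of = etree.SubElement(root, f"{{{HL7_NS}}}subjectOf")
        for app in drug.app_numbers:
            approval = etree.SubElement(subject_of, f"{{{HL7_NS}}}approval")
            etree.SubElement(
                approval,
                f"{{{HL7_NS}}}id",
                extension=f"NDA{app}",
                root="2.16.840.1.113883.3.150",
            )
            etree.SubElement(approval, f"{{{HL7_NS}}}code", code="C73594", displayName="NDA")
    component = etree.SubElement(root, f"{{{HL7_NS}}}component")
    body = etree.SubElement(component, f"{{{HL7_NS}}}structuredBody")
    order = [k for k in _SPL_LOINC if k is not SectionKind.pharmacokinetics]
    for kind in order:
        if kind not in sections:
            continue
        _spl_section(body, kind, sections[kind])
    if pk_text is not None:
        _spl_section(body, SectionKind.pharmacokinetics, pk_text)
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)


def _spl_section(body, kind: SectionKind, text: str) -> None:
    code, display = _SPL_LOINC[kind]
    comp = etree.SubElement(body, f"{{{HL7_NS}}}component")
    section = etree.SubElement(comp, f"{{{HL7_NS}}}section")
    etree.SubElement(
        section, f"{{{HL7_NS}}}code", code=code, codeSystem="2.16.840.1.113883.6.1", displayName=display
    )
    title = etree.SubElement(section, f"{{{HL7_NS}}}title")
    title.text = display.replace(" SECTION", "")
    text_el = etree.SubElement(section, f"{{{HL7_NS}}}text")
    for para in text.split("\n\n"):
        p = etree.SubElement(text_el, f"{{{HL7_NS}}}paragraph")
        p.text = para


def generate_spl_corpus(spec: CorpusSpec, outdir: Path) -> dict:
    """Write SPL-style XML files + ground-truth manifest entries.

    One file per (drug, version); versions share the Set ID with increasing
    effective dates and version numbers. Deterministic given the spec.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(f"{spec.seed}:spl")
    manifest: dict[str, dict] = {}
    top_kinds = [k for k in _SPL_LOINC if k is not SectionKind.pharmacokinetics]
    for drug in make_drugs(spec):
        if "dailymed" not in drug.sources:
            continue
        for version in range(1, drug.n_versions + 1):
            sections = _choose_sections(drug, rng, top_kinds, spec.p_section)
            admef = _choose_sections(drug, rng, list(ADMEF_SECTIONS), spec.p_section, force_some=False)
            pk_text = None
            expected = dict(sections)
            if admef or rng.random() < spec.p_section:
                preamble = (
                    normalize_text(_PK_PREAMBLE.format(drug=drug.name))
                    if rng.random() < 0.6
                    else ""
                )
                if admef:
                    pk_text, pk_expected = _pk_block(admef, preamble, rng)
                    expected.update(pk_expected)
                elif preamble:
                    pk_text = preamble
                    expected[SectionKind.pharmacokinetics] = preamble
            eff_date = drug.base_date + timedelta(days=90 * (version - 1))
            fname = f"{drug.set_id}_v{version}.xml"
            (outdir / fname).write_bytes(
                _spl_xml(drug, version, eff_date, sections, pk_text)
            )
            manifest[fname] = {
                "set_id": drug.set_id,
                "version": version,
                "effective_date": eff_date.isoformat(),
                "app_numbers": [] if drug.unmapped else list(drug.app_numbers),
                "sections": {k.value: v for k, v in expected.items()},
            }
    return manifest


# --- Free-text labels ---------------------------------------------------------


def _noisy_lines(lines: list[str], rate: float, rng: random.Random) -> list[str]:
    if rate <= 0:
        return lines
    out: list[str] = []
    page = 1
    for ln in lines:
        words = ln.split()
        if ln and rng.random() < rate and len(words) >= 8:
            cut = rng.randrange(4, len(words) - 3)  # both halves ≥4 words
            out.append(" ".join(words[:cut]))
            out.append(" ".join(words[cut:]))
        else:
            out.append(ln)
        if rng.random() < rate / 3:
            out.append(f"Label text continues on page {page}")
            page += 1
    return out


def generate_freetext_labels(spec: CorpusSpec, outdir: Path) -> dict:
    """Write free-text label files (Drugs@FDA style) + manifest entries.

    Heading case and outline numbering are randomized; ``spec.heading_noise``
    injects PDF-conversion artifacts (stray line breaks, repeated page
    headers). Files follow the ``NDAnnnnnn_YYYYMMDD.txt`` naming convention
    except for unmapped documents.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(f"{spec.seed}:freetext")
    manifest: dict[str, dict] = {}
    top_kinds = [k for k in _FREETEXT_HEADINGS if k is not SectionKind.pharmacokinetics]
    unmapped_count = 0
    for drug in make_drugs(spec):
        if "drugs_at_fda" not in drug.sources:
            continue
        n_versions = min(drug.n_versions, 2)
        for version in range(1, n_versions + 1):
            sections = _choose_sections(drug, rng, top_kinds, spec.p_section)
            admef = _choose_sections(drug, rng, list(ADMEF_SECTIONS), spec.p_section, force_some=False)
            expected = dict(sections)
            lines: list[str] = []
            outline = 1

            def heading(text: str) -> str:
                nonlocal outline
                style = rng.randrange(3)
                h = text.upper() if style == 0 else text.title()
                if style == 2:
                    h = f"{outline} {h}"
                outline += 1
                return h

            for kind, content in sections.items():
                lines.append(heading(_FREETEXT_HEADINGS[kind]))
                lines.extend(content.split("\n"))
                lines.append("")
            if admef:
                preamble = (
                    normalize_text(_PK_PREAMBLE.format(drug=drug.name))
                    if rng.random() < 0.6
                    else ""
                )
                pk_text, pk_expected = _pk_block(admef, preamble, rng)
                expected.update(pk_expected)
                lines.append(heading(_FREETEXT_HEADINGS[SectionKind.pharmacokinetics]))
                lines.extend(pk_text.split("\n"))
                lines.append("")
            lines = _noisy_lines(lines, spec.heading_noise, rng)
            text = "\n".join(lines).rstrip() + "\n"
            eff_date = drug.base_date + timedelta(days=120 * (version - 1))
            if drug.unmapped:
                fname = f"label_{unmapped_count:03d}.txt"
                unmapped_count += 1
                app_numbers: list[str] = []
                date_str = None
            else:
                fname = f"NDA{drug.app_numbers[0]}_{eff_date.strftime('%Y%m%d')}.txt"
                app_numbers = [drug.app_numbers[0]]
                date_str = eff_date.isoformat()
            (outdir / fname).write_text(text, encoding="utf-8")
            manifest[fname] = {
                "app_numbers": app_numbers,
                "effective_date": date_str,
                "sections": {k.value: v for k, v in expected.items()},
            }
    return manifest


# --- DrugBank datafile --------------------------------------------------------


def generate_drugbank_xml(spec: CorpusSpec, outpath: Path) -> dict:
    """Write a single DrugBank-style datafile + manifest entries."""
    outpath = Path(outpath)
    outpath.parent.mkdir(parents=True, exist_ok=True)
    rng = random.Random(f"{spec.seed}:drugbank")
    root = etree.Element(f"{{{DRUGBANK_NS}}}drugbank", nsmap={None: DRUGBANK_NS})
    manifest: dict[str, dict] = {}
    kinds = list(_DRUGBANK_TAGS)
    for drug in make_drugs(spec):
        if "drugbank" not in drug.sources:
            continue
        el = etree.SubElement(root, f"{{{DRUGBANK_NS}}}drug", type="small molecule")
        id_el = etree.SubElement(el, f"{{{DRUGBANK_NS}}}drugbank-id", primary="true")
        id_el.text = drug.drugbank_id
        sec_id = etree.SubElement(el, f"{{{DRUGBANK_NS}}}drugbank-id")
        sec_id.text = drug.drugbank_id.replace("DB", "APRD")
        name_el = etree.SubElement(el, f"{{{DRUGBANK_NS}}}name")
        name_el.text = drug.name
        sections = _choose_sections(drug, rng, kinds, spec.p_section)
        for kind, tag in _DRUGBANK_TAGS.items():
            field_el = etree.SubElement(el, f"{{{DRUGBANK_NS}}}{tag}")
            if kind in sections:
                field_el.text = sections[kind]
        products = etree.SubElement(el, f"{{{DRUGBANK_NS}}}products")
        if not drug.unmapped:
            for app in drug.app_numbers:
                product = etree.SubElement(products, f"{{{DRUGBANK_NS}}}product")
                pname = etree.SubElement(product, f"{{{DRUGBANK_NS}}}name")
                pname.text = f"{drug.name} tablets"
                num = etree.SubElement(product, f"{{{DRUGBANK_NS}}}fda-application-number")
                num.text = f"NDA{app}"
        manifest[drug.drugbank_id] = {
            "app_numbers": [] if drug.unmapped else list(drug.app_numbers),
            "sections": {k.value: v for k, v in sections.items()},
        }
    outpath.write_bytes(
        etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)
    )
    return manifest


# --- Orange Book products file ------------------------------------------------


def generate_orange_book(spec: CorpusSpec, outpath: Path) -> dict:
    """Write an Orange Book-style products file; NDA rows for in-reference drugs.

    Includes duplicate product rows for the same application and ANDA rows,
    both of which the parser must collapse/exclude.
    """
    outpath = Path(outpath)
    outpath.parent.mkdir(parents=True, exist_ok=True)
    rng = random.Random(f"{spec.seed}:orangebook")
    rows: list[str] = ["Ingredient~Trade_Name~Appl_Type~Appl_No~Approval_Date"]
    nda: list[str] = []
    for drug in make_drugs(spec):
        if not drug.in_reference:
            continue
        for app in drug.app_numbers:
            nda.append(app)
            n_rows = rng.choice((1, 2))  # duplicate product rows collapse
            for i in range(n_rows):
                rows.append(
                    f"{drug.name.upper()}~{drug.name.upper()} {5 * (i + 1)}MG~N~{app}~{drug.base_date.isoformat()}"
                )
        if rng.random() < 0.4:
            rows.append(f"{drug.name.upper()}~GENERIC {drug.name.upper()}~A~{rng.randrange(70000, 99999):06d}~{drug.base_date.isoformat()}")
    outpath.write_text("\n".join(rows) + "\n", encoding="utf-8")
    return {"nda_numbers": sorted(set(nda))}


# --- Whole-corpus convenience -------------------------------------------------


def generate_corpus(spec: CorpusSpec, outdir: Path) -> dict:
    """Generate all four source fixtures under ``outdir`` plus manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "spec": spec.to_dict(),
        "spl": generate_spl_corpus(spec, outdir / "spl"),
        "freetext": generate_freetext_labels(spec, outdir / "freetext"),
        "drugbank": generate_drugbank_xml(spec, outdir / "drugbank.xml"),
        "orange_book": generate_orange_book(spec, outdir / "products.txt"),
        "drugs": [
            {
                "name": d.name,
                "app_numbers": d.app_numbers,
                "set_id": d.set_id,
                "drugbank_id": d.drugbank_id,
                "in_reference": d.in_reference,
                "unmapped": d.unmapped,
                "n_versions": d.n_versions,
                "sources": d.sources,
            }
            for d in make_drugs(spec)
        ],
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
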