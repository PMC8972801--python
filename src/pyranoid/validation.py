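"""Per-sugar model validation: anomeric configuration, chirality,
puckering amplitude and ring conformation, combined into a yes/no/check
verdict.

A sugar is diagnosed "yes" when all four criteria match the expectations
for its component code; "check" when the ring conformation is the *only*
failing criterion (a high-energy pucker that the user should verify
against the density); and "no" otherwise.  The ring conformation is a
powerful validation metric precisely because refinement cannot fake it
by trading off bond-length and bond-angle distortions: a boat can have
near-ideal bonds and angles and still be wrong.

Expectations follow the low-energy-chair rule: saturated D-pyranoses are
expected in the 4C1 chair and L-pyranoses in 1C4, with per-component
overrides (e.g. ketopyranoses, unsaturated rings).  A default table for
the most frequently modelled pyranosides ships with the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .cif_io import ChiralRestraint, MonomerCoordinates, RestraintDictionary
from .puckering import (
    ConformerLabel,
    PuckerCoordinates,
    classify,
    conformer_by_name,
    cremer_pople,
    is_high_energy,
)
from .ring_geometry import RingAtoms, detect_ring

#: puckering-amplitude window (Angstrom) bracketing physically sensible
#: six-ring puckers; typical chairs sit at ~0.55-0.63 A
Q_WINDOW = (0.35, 0.9)


@dataclass(frozen=True)
class Expectation:
    """What a correctly modelled instance of one component looks like."""

    comp_id: str
    series: str  # "D" | "L"
    expected_conformer: str = ""
    expected_anomer: str = "beta"  # "alpha" | "beta"
    saturated: bool = True
    #: sign of (anomeric substituent) . (ring normal) for a correct model;
    #: derived from series/anomer when 0 (alpha-D and beta-L point to the
    #: negative face), overridable for ketoses
    anomeric_face: int = 0

    def conformer(self) -> ConformerLabel:
        name = self.expected_conformer
        if not name:
            name = "4C1" if self.series == "D" else "1C4"
        return conformer_by_name(name)

    def expected_sign(self) -> int:
        if self.anomeric_face:
            return self.anomeric_face
        alpha = self.expected_anomer == "alpha"
        if self.series == "D":
            return -1 if alpha else 1
        return 1 if alpha else -1


@dataclass(frozen=True)
class ChiralityViolation:
    centre: str
    kind: str  # "sign" | "incomplete"
    expected: str = ""
    observed: str = ""


@dataclass
class Diagnosis:
    """Validation verdict for one sugar with per-criterion reasons."""

    verdict: str  # "yes" | "no" | "check"
    reasons: list[tuple[str, bool, str]]
    pucker: PuckerCoordinates
    label: ConformerLabel

    def failed(self) -> list[str]:
        return [name for name, ok, _ in self.reasons if not ok]


# ---------------------------------------------------------------------------
# expectation table


def load_expectations(path: str | Path | None = None) -> dict[str, Expectation]:
    """Load an expectation table (TSV), defaulting to the shipped one.

    Columns: comp_id, series, expected_conformer, expected_anomer,
    saturated, anomeric_face.
    """
    if path is None:
        with resources.files("pyranoid").joinpath("data/expectations.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    out = {}
    for row in df.itertuples(index=False):
        out[row.comp_id] = Expectation(
            comp_id=row.comp_id,
            series=row.series,
            expected_conformer=str(getattr(row, "expected_conformer", "") or ""),
            expected_anomer=row.expected_anomer,
            saturated=bool(getattr(row, "saturated", True)),
            anomeric_face=int(getattr(row, "anomeric_face", 0) or 0),
        )
    return out


DEFAULT_EXPECTATIONS: dict[str, Expectation] = {}


def _default_expectations() -> dict[str, Expectation]:
    if not DEFAULT_EXPECTATIONS:
        DEFAULT_EXPECTATIONS.update(load_expectations())
    return DEFAULT_EXPECTATIONS


# ---------------------------------------------------------------------------
# criteria


def check_chirality(
    c: MonomerCoordinates, d: RestraintDictionary
) -> list[ChiralityViolation]:
    """Compare each chiral centre's signed volume against its restraint.

    The sign of the scalar triple product of the three centre->neighbour
    vectors must match the restraint ("both" always passes).  A missing
    atom yields an "incomplete" violation rather than an error.
    """
    out = []
    for ch in d.chiralities:
        if ch.sign == "both":
            continue
        atoms = (ch.centre, *ch.neighbours)
        if any(a not in c for a in atoms):
            out.append(ChiralityViolation(ch.centre, "incomplete"))
            continue
        observed = chiral_sign(c, ch)
        if observed != ch.sign:
            out.append(
                ChiralityViolation(ch.centre, "sign", ch.sign, observed)
            )
    return out


def chiral_sign(c: MonomerCoordinates, ch: ChiralRestraint) -> str:
    """Observed volume sign ("positive"/"negative") at one centre."""
    centre = c[ch.centre]
    v1, v2, v3 = (c[n] - centre for n in ch.neighbours)
    vol = float(np.dot(v1, np.cross(v2, v3)))
    return "positive" if vol > 0 else "negative"


def _ring_normal(c: MonomerCoordinates, r: RingAtoms) -> np.ndarray:
    """CP mean-plane normal, oriented by the ring traversal."""
    pts = c.array(list(r))
    centred = pts - pts.mean(axis=0)
    j = np.arange(6)
    r1 = (centred * np.sin(2 * np.pi * j / 6)[:, None]).sum(axis=0)
    r2 = (centred * np.cos(2 * np.pi * j / 6)[:, None]).sum(axis=0)
    n = np.cross(r1, r2)
    norm = np.linalg.norm(n)
    if norm == 0:
        raise ValueError("degenerate ring")
    return n / norm


def anomeric_substituent(
    d: RestraintDictionary, r: RingAtoms
) -> str | None:
    """Name of the exocyclic O (or N/C stand-in) on the anomeric carbon."""
    ring_set = set(r)
    candidates: list[tuple[int, str, str]] = []
    for b in d.bonds:
        other = None
        if b.atom1 == r.anomeric and b.atom2 not in ring_set:
            other = b.atom2
        elif b.atom2 == r.anomeric and b.atom1 not in ring_set:
            other = b.atom1
        if other is None:
            continue
        el = d.element_of(other).upper()
        if el in ("H", "D"):
            continue
        rank = {"O": 0, "N": 1}.get(el, 2)
        candidates.append((rank, other, el))
    if not candidates:
        return None
    candidates.sort()
    return candidates[0][1]


def check_anomeric(
    c: MonomerCoordinates,
    r: RingAtoms,
    d: RestraintDictionary,
    e: Expectation,
) -> tuple[str, str]:
    """("pass"|"fail"|"indeterminate", detail) for the anomeric centre.

    The anomeric substituent's disposition is taken as the sign of its
    bond vector against the traversal-oriented ring normal -- in the
    expected chair, an axial alpha-D substituent points to the negative
    face, an equatorial beta-D substituent tilts to the positive face.
    The sign is a stereodescriptor: it is stable under ring-conformation
    changes, so a boat-only distortion does not masquerade as a wrong
    anomer.  A missing substituent (e.g. a glycosidically linked atom
    not in the residue) is indeterminate and treated as a pass with a
    warning.
    """
    sub = anomeric_substituent(d, r)
    if sub is None or sub not in c:
        return "indeterminate", "anomeric substituent absent; cannot verify anomer"
    v = c[sub] - c[r.anomeric]
    nrm = np.linalg.norm(v)
    if nrm == 0:
        return "indeterminate", "zero-length anomeric bond"
    sign = 1 if float(v / nrm @ _ring_normal(c, r)) >= 0 else -1
    if sign == e.expected_sign():
        return "pass", f"{e.expected_anomer} anomer consistent ({sub})"
    return "fail", (
        f"wrong anomer: {sub} on the "
        f"{'positive' if sign > 0 else 'negative'} face but expected "
        f"{e.expected_anomer} for the {e.series}-series"
    )


# ---------------------------------------------------------------------------
# verdict


def diagnose(
    c: MonomerCoordinates,
    d: RestraintDictionary,
    e: Expectation | None = None,
    *,
    q_window: tuple[float, float] = Q_WINDOW,
) -> Diagnosis:
    """Run the four validation criteria and combine them into a verdict.

    Criteria: (1) anomeric configuration, (2) chirality of all restrained
    centres, (3) puckering amplitude Q inside ``q_window``, (4) ring
    conformation equal to the expected low-energy conformer.  Verdict:
    "yes" iff all pass; "check" iff conformation is the sole failure;
    "no" otherwise.
    """
    if e is None:
        e = _default_expectations().get(
            d.comp_id, Expectation(comp_id=d.comp_id, series="D")
        )
    ring = detect_ring(d)
    pucker = cremer_pople(c, ring)
    label = classify(pucker)

    anomeric_status, anomeric_detail = check_anomeric(c, ring, d, e)
    chir_violations = check_chirality(c, d)
    q_ok = q_window[0] <= pucker.Q <= q_window[1]
    conf_ok = (not pucker.is_planar) and not is_high_energy(label, e.conformer())

    reasons = [
        ("anomeric", anomeric_status != "fail", anomeric_detail),
        (
            "chirality",
            not chir_violations,
            "; ".join(
                f"{v.centre}: {v.kind}" + (f" ({v.observed} vs {v.expected})" if v.kind == "sign" else "")
                for v in chir_violations
            )
            or "all chiral centres consistent",
        ),
        (
            "amplitude",
            q_ok,
            f"Q = {pucker.Q:.3f} A (window {q_window[0]}-{q_window[1]} A)",
        ),
        (
            "conformation",
            conf_ok,
            f"{label.name} (expected {e.conformer().name})",
        ),
    ]
    return Diagnosis(verdict=verdict_rule([ok for _, ok, _ in reasons]),
                     reasons=reasons, pucker=pucker, label=label)


def verdict_rule(passes: list[bool]) -> str:
    """Combine [anomeric, chirality, amplitude, conformation] passes.

    "yes" iff all pass; "check" iff the conformation criterion (last) is
    the only failure; otherwise "no".
    """
    anomeric, chirality, amplitude, conformation = passes
    if all(passes):
        return "yes"
    if anomeric and chirality and amplitude and not conformation:
        return "check"
    return "no"


# ---------------------------------------------------------------------------
# batch reporting


def batch_report(
    models: list[tuple[MonomerCoordinates, RestraintDictionary]],
    expectations: dict[str, Expectation] | None = None,
    resolutions: list[float] | None = None,
    n_bins: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Diagnose many sugars; return (verdict counts, per-sugar rows).

    When ``resolutions`` is given (one value per model), the counts are
    additionally stratified into ``n_bins`` equal-count resolution bins.
    """
    expectations = expectations or _default_expectations()
    rows = []
    for i, (c, d) in enumerate(models):
        e = expectations.get(d.comp_id)
        diag = diagnose(c, d, e)
        row = {
            "comp_id": d.comp_id,
            "chain": c.chain,
            "seqnum": c.seqnum,
            "Q": diag.pucker.Q,
            "theta": diag.pucker.theta,
            "phi": diag.pucker.phi,
            "conformer": diag.label.name,
            "verdict": diag.verdict,
            "failed": ",".join(diag.failed()),
        }
        if resolutions is not None:
            row["resolution"] = resolutions[i]
        rows.append(row)
    per_sugar = pd.DataFrame(rows)

    verdicts = ["yes", "check", "no"]
    if per_sugar.empty:
        counts = pd.DataFrame({"verdict": verdicts, "count": [0, 0, 0]})
        return counts, per_sugar

    if resolutions is not None:
        per_sugar["resolution_bin"] = pd.qcut(
            per_sugar["resolution"], q=n_bins, duplicates="drop"
        )
        counts = (
            per_sugar.groupby(["resolution_bin", "verdict"], observed=False)
            .size()
            .reset_index(name="count")
        )
    else:
        counts = (
            per_sugar["verdict"]
            .value_counts()
            .reindex(verdicts, fill_value=0)
            .rename_axis("verdict")
            .reset_index(name="count")
        )
    return counts, per_sugar
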