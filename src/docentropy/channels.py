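"""Channel nomenclature for the 16-channel 10-20 montage and its
affected/unaffected relabeling.

Left-hemisphere electrodes carry odd indices (FP1, F3, ...), right-hemisphere
even. After the affected side is determined, channels are relabeled with _A
(affected) / _U (unaffected) subscripts; the temporal chain F7/F8, T3/T4,
T5/T6 becomes AT (anterior temporal), MT (middle temporal), PT (posterior
temporal).
"""

from __future__ import annotations

from dataclasses import dataclass

#: (region, left electrode, right electrode) in canonical order.
REGIONS: list[tuple[str, str, str]] = [
    ("FP", "FP1", "FP2"),
    ("F", "F3", "F4"),
    ("C", "C3", "C4"),
    ("P", "P3", "P4"),
    ("O", "O1", "O2"),
    ("AT", "F7", "F8"),
    ("MT", "T3", "T4"),
    ("PT", "T5", "T6"),
]

#: Canonical 10-20 label order used for raw recordings.
RAW_LABELS: list[str] = [lab for _, l, r in REGIONS for lab in (l, r)]

#: Canonical relabeled order: FP_A, FP_U, F_A, F_U, ..., PT_A, PT_U.
RELABELED: list[str] = [f"{reg}_{s}" for reg, _, _ in REGIONS for s in ("A", "U")]

AFFECTED_CHANNELS: list[str] = [c for c in RELABELED if c.endswith("_A")]
UNAFFECTED_CHANNELS: list[str] = [c for c in RELABELED if c.endswith("_U")]

LEFT_LABELS: list[str] = [l for _, l, _ in REGIONS]
RIGHT_LABELS: list[str] = [r for _, _, r in REGIONS]

#: Modern 10-10 synonyms accepted on input for the temporal chain.
SYNONYMS: dict[str, str] = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"}


def normalize_label(label: str) -> str:
    """Map a raw channel label to its canonical 10-20 name.

    Case-insensitive; T7/T8/P7/P8 are accepted as synonyms of T3/T4/T5/T6.
    Raises ``ValueError`` for labels outside the 16-channel montage.
    """
    lab = label.strip().upper()
    lab = SYNONYMS.get(lab, lab)
    if lab not in RAW_LABELS:
        raise ValueError(f"unknown channel label {label!r}; expected one of {RAW_LABELS}")
    return lab


def side_of(label: str) -> str:
    """Hemisphere ('left' or 'right') of a canonical 10-20 label."""
    lab = normalize_label(label)
    return "left" if lab in LEFT_LABELS else "right"


def relabel_map(affected_side: str) -> dict[str, str]:
    """Mapping canonical 10-20 label -> relabeled _A/_U name."""
    if affected_side not in ("left", "right"):
        raise ValueError("affected_side must be 'left' or 'right'")
    out: dict[str, str] = {}
    for reg, left, right in REGIONS:
        if affected_side == "left":
            out[left], out[right] = f"{reg}_A", f"{reg}_U"
        else:
            out[left], out[right] = f"{reg}_U", f"{reg}_A"
    return out


def pair_name(template: str, target: str) -> str:
    return f"{template}-{target}"


@dataclass(frozen=True)
class PairSpec:
    """The ten designated cross-entropy channel pairs.

    The first element of every pair is the central electrode (C_A or C_U),
    which supplies the template sequences; cross-approximate entropy is
    asymmetric, so the direction matters and is fixed here.
    """

    local_affected: tuple[tuple[str, str], ...] = (
        ("C_A", "P_A"), ("C_A", "F_A"), ("C_A", "MT_A"))
    local_unaffected: tuple[tuple[str, str], ...] = (
        ("C_U", "P_U"), ("C_U", "F_U"), ("C_U", "MT_U"))
    distant_affected: tuple[tuple[str, str], ...] = (
        ("C_A", "FP_A"), ("C_A", "O_A"))
    distant_unaffected: tuple[tuple[str, str], ...] = (
        ("C_U", "FP_U"), ("C_U", "O_U"))

    def __post_init__(self) -> None:
        for pair in self.all_pairs:
            if not pair[0].startswith("C_"):
                raise ValueError(f"template channel of {pair} must be central (C_A/C_U)")
        if len(set(self.all_pairs)) != len(self.all_pairs):
            raise ValueError("duplicate channel pairs")

    @property
    def all_pairs(self) -> tuple[tuple[str, str], ...]:
        return (self.local_affected + self.local_unaffected
                + self.distant_affected + self.distant_unaffected)

    @property
    def affected(self) -> tuple[tuple[str, str], ...]:
        return self.local_affected + self.distant_affected

    @property
    def unaffected(self) -> tuple[tuple[str, str], ...]:
        return self.local_unaffected + self.distant_unaffected

    @property
    def pair_names(self) -> list[str]:
        return [pair_name(*p) for p in self.all_pairs]

    def groups(self) -> dict[str, list[str]]:
        """Pair names grouped into the four local/distant x side summaries."""
        return {
            "local_affected": [pair_name(*p) for p in self.local_affected],
            "local_unaffected": [pair_name(*p) for p in self.local_unaffected],
            "distant_affected": [pair_name(*p) for p in self.distant_affected],
            "distant_unaffected": [pair_name(*p) for p in self.distant_unaffected],
        }


DEFAULT_PAIRS = PairSpec()
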