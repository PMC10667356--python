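"""Probe geometry: two 3x5 optode grids, 44 channels, ROI channel map.

Each hemisphere carries a 3x5 optode grid (8 emitters, 7 detectors in a
checkerboard) with 30 mm spacing; every emitter-detector nearest-neighbour
pair defines a measurement channel at the pair midpoint, giving 22 channels
per probe set (channels 1-22 left, 23-44 right).

The channel -> region-of-interest map required by the group analyses is a
user-supplied config in any real use.  ``default_roi_map`` ships a synthetic
stand-in that carves each probe grid into anatomically plausible blocks
(inferior frontal gyrus, dorsolateral prefrontal cortex, inferior parietal
lobule, motor cortex per hemisphere).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

OPTODE_SPACING_MM = 30.0
ROI_LABELS = (
    "left_IFG",
    "right_IFG",
    "left_DLPFC",
    "right_DLPFC",
    "left_IPL",
    "right_IPL",
    "left_MC",
    "right_MC",
)


@dataclass
class Montage:
    """Channel geometry for both probe sets.

    channel_ids are 1-based.  ``coords_mm`` holds 2-D scalp-plane channel
    positions; the left probe occupies negative x, the right positive x,
    with y increasing from inferior/anterior row to superior/posterior row.
    """

    channel_ids: np.ndarray  # (44,)
    coords_mm: np.ndarray  # (44, 2)
    probe_set: np.ndarray  # (44,) "left"/"right"
    channel_optodes: dict[int, tuple[str, str]]  # channel -> (emitter, detector)

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    def hemisphere(self, channel: int) -> str:
        return str(self.probe_set[channel - 1])

    def adjacency(self) -> dict[int, set[int]]:
        """Channels are neighbours iff they share an optode (same probe)."""
        adj: dict[int, set[int]] = {int(c): set() for c in self.channel_ids}
        for c1 in self.channel_ids:
            o1 = set(self.channel_optodes[int(c1)])
            for c2 in self.channel_ids:
                if c1 != c2 and o1 & set(self.channel_optodes[int(c2)]):
                    adj[int(c1)].add(int(c2))
        return adj


def _probe_channels(x_offset: float, mirror: bool, optode_prefix: str):
    """One 3x5 grid: optode positions, channel midpoints, optode pairs."""
    cols, rows = 5, 3
    positions = {}
    kind = {}
    for r in range(rows):
        for c in range(cols):
            x = c * OPTODE_SPACING_MM
            if mirror:
                x = (cols - 1) * OPTODE_SPACING_MM - x
            positions[(r, c)] = (x_offset + x, r * OPTODE_SPACING_MM)
            # checkerboard: emitter on even parity, detector on odd
            kind[(r, c)] = "E" if (r + c) % 2 == 0 else "D"

    def name(rc):
        r, c = rc
        return f"{optode_prefix}{kind[rc]}{r}{c}"

    channels = []
    # horizontal pairs row-major, then vertical pairs between row bands:
    # ordering is stable and documented, not vendor numbering.
    for r in range(rows):
        for c in range(cols - 1):
            channels.append(((r, c), (r, c + 1)))
        if r < rows - 1:
            for c in range(cols):
                channels.append(((r, c), (r + 1, c)))
    # reorder to: row0 horizontals, row0-1 verticals, row1 horizontals, ...
    coords = []
    pairs = []
    for a, b in channels:
        (xa, ya), (xb, yb) = positions[a], positions[b]
        coords.append(((xa + xb) / 2.0, (ya + yb) / 2.0))
        ea, eb = name(a), name(b)
        emitter, detector = (ea, eb) if kind[a] == "E" else (eb, ea)
        pairs.append((emitter, detector))
    return np.asarray(coords), pairs


def build_montage(hemisphere_gap_mm: float = 140.0) -> Montage:
    """Standard montage: 22 channels per hemisphere, 30 mm optode spacing."""
    left_coords, left_pairs = _probe_channels(
        x_offset=-(hemisphere_gap_mm / 2 + 4 * OPTODE_SPACING_MM),
        mirror=False,
        optode_prefix="L",
    )
    right_coords, right_pairs = _probe_channels(
        x_offset=hemisphere_gap_mm / 2, mirror=True, optode_prefix="R"
    )
    coords = np.vstack([left_coords, right_coords])
    ids = np.arange(1, 45)
    probe = np.array(["left"] * 22 + ["right"] * 22)
    optodes = {int(i): p for i, p in zip(ids, left_pairs + right_pairs)}
    return Montage(
        channel_ids=ids, coords_mm=coords, probe_set=probe, channel_optodes=optodes
    )


def default_roi_map() -> dict[str, list[int]]:
    """Synthetic stand-in channel -> ROI assignment.

    The original study derived channel anatomy from probabilistic template
    registration; that mapping is figure-only content and must be supplied
    as config for any real dataset.  This stand-in carves each 22-channel
    probe grid into four contiguous blocks: inferior-anterior channels to
    the IFG, superior-anterior to the DLPFC, superior-posterior to the MC,
    and inferior-posterior to the IPL.
    """
    # left probe channel ids 1..22 in band order: 1-4 inferior horizontals,
    # 5-9 lower verticals, 10-13 middle horizontals, 14-18 upper verticals,
    # 19-22 superior horizontals; anterior = low column index.
    left = {
        "left_IFG": [1, 2, 5, 6],
        "left_DLPFC": [10, 11, 14, 15],
        "left_MC": [12, 16, 19, 20],
        "left_IPL": [3, 4, 7, 8, 9, 13, 17, 18, 21, 22],
    }
    out = dict(left)
    for roi, chans in left.items():
        out["right" + roi[4:]] = [c + 22 for c in chans]
    return {roi: out[roi] for roi in ROI_LABELS}


def validate_roi_map(roi_map: dict[str, list[int]], montage: Montage) -> None:
    """Check ROI map invariants: 8 ROIs, valid non-empty channel sets,
    hemisphere-consistent assignments."""
    if set(roi_map) != set(ROI_LABELS):
        raise ValueError(f"ROI map must define exactly the ROIs {ROI_LABELS}")
    for roi, chans in roi_map.items():
        if not chans:
            raise ValueError(f"ROI {roi} has no channels")
        side = roi.split("_")[0]
        for c in chans:
            if not 1 <= c <= montage.n_channels:
                raise ValueError(f"ROI {roi} references invalid channel {c}")
            if montage.hemisphere(c) != side:
                raise ValueError(
                    f"ROI {roi} includes channel {c} from the "
                    f"{montage.hemisphere(c)} probe set"
                )


def roi_map_to_yaml(roi_map: dict[str, list[int]], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({k: list(map(int, v)) for k, v in roi_map.items()}, fh)


def roi_map_from_yaml(path) -> dict[str, list[int]]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {str(k): [int(c) for c in v] for k, v in raw.items()}


def montage_to_dict(montage: Montage) -> dict:
    """JSON/YAML-serializable sidecar description of the montage."""
    return {
        "channels": [
            {
                "id": int(c),
                "x_mm": float(montage.coords_mm[i, 0]),
                "y_mm": float(montage.coords_mm[i, 1]),
                "probe_set": str(montage.probe_set[i]),
                "emitter": montage.channel_optodes[int(c)][0],
                "detector": montage.channel_optodes[int(c)][1],
            }
            for i, c in enumerate(montage.channel_ids)
        ],
        "optode_spacing_mm": OPTODE_SPACING_MM,
    }
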