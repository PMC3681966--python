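"""Standard scalp layouts on the unit head circle.

Positions come from the extended 10-05 electrode system as shipped with
:mod:`mne`; 3-D head-frame coordinates are projected to a 2-D head circle
by azimuthal-equidistant projection, with the vertex (Cz) at the origin and
the head circumference at radius 1.  High-density 128-channel caps have
no single canonical label list, so the 128-channel set here is a
best-effort standard 10-05 subset.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

#: Occipito-parietal channels used as classifier features.
OCCIPITO_PARIETAL = (
    "C1", "CZ", "C2",
    "CP1", "CP3", "CPZ", "CP2", "CP4",
    "P1", "PZ", "P4",
    "PO9", "PO7", "PO5", "PO3", "POZ", "PO4", "PO6", "PO8", "PO10",
    "O1", "OZ", "O2",
)

#: Standard 64-channel 10-10 cap label set (upper-case).
LABELS_64 = (
    "FP1", "FPZ", "FP2", "AF3", "AF4", "F7", "F5", "F3", "F1", "FZ", "F2",
    "F4", "F6", "F8", "FT7", "FC5", "FC3", "FC1", "FCZ", "FC2", "FC4",
    "FC6", "FT8", "T7", "C5", "C3", "C1", "CZ", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6", "TP8", "P7",
    "P5", "P3", "P1", "PZ", "P2", "P4", "P6", "P8", "PO7", "PO5", "PO3",
    "POZ", "PO4", "PO6", "PO8", "O1", "OZ", "O2", "PO9", "PO10", "P9",
    "P10",
)

#: Compact 16-channel set used by the desk-scale synthetic datasets; the
#: posterior half intersects the occipito-parietal classifier roster.
LABELS_16 = (
    "FP1", "FP2", "F3", "F4", "C1", "CZ", "C2", "CP1", "CPZ", "CP2",
    "P1", "PZ", "P4", "O1", "OZ", "O2",
)


def _standard_positions() -> dict[str, np.ndarray]:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            mont = mne.channels.make_standard_montage("standard_1005")
        except ValueError:  # renamed in newer mne
            mont = mne.channels.make_standard_montage("colin27_1005")
    pos = mont.get_positions()["ch_pos"]
    return {name.upper(): np.asarray(p, float) for name, p in pos.items()}


def _project_azimuthal(p3d: np.ndarray) -> np.ndarray:
    """Azimuthal-equidistant projection of a 3-D head point to 2-D."""
    x, y, z = p3d
    r = np.linalg.norm(p3d)
    if r == 0:
        return np.zeros(2)
    polar = np.arccos(np.clip(z / r, -1, 1))  # angle from vertex
    az = np.arctan2(y, x)
    # pi/2 polar angle (the ear/inion ring) maps to radius 1
    rho = polar / (np.pi / 2)
    return np.array([rho * np.cos(az), rho * np.sin(az)])


_CACHE: dict[str, pd.DataFrame] = {}


def standard_montage(n_channels: int = 64) -> pd.DataFrame:
    """Return a DataFrame (label, x, y) for a standard cap.

    Parameters
    ----------
    n_channels : {16, 64, 128}
        Cap size.  16 is a compact desk-scale subset, 64 the standard
        10-10 cap, 128 a best-effort extended 10-05 layout.
    """
    key = str(n_channels)
    if key in _CACHE:
        return _CACHE[key].copy()
    all_pos = _standard_positions()
    if n_channels == 16:
        labels = list(LABELS_16)
    elif n_channels == 64:
        labels = list(LABELS_64)
    elif n_channels == 128:
        labels = list(LABELS_64)
        # extend with further 10-05 sites, nearest-to-vertex first for a
        # roughly uniform high-density cap
        extra = [
            (np.linalg.norm(_project_azimuthal(p)), lab)
            for lab, p in all_pos.items()
            if lab not in labels and not lab.startswith(("T9", "T10", "A"))
        ]
        for _, lab in sorted(extra):
            labels.append(lab)
            if len(labels) == 128:
                break
    else:
        raise ValueError(f"no standard montage for {n_channels} channels")
    rows = []
    for lab in labels:
        if lab not in all_pos:
            raise KeyError(f"label {lab} not in the 10-05 position set")
        xy = _project_azimuthal(all_pos[lab])
        rows.append((lab, xy[0], xy[1]))
    df = pd.DataFrame(rows, columns=["label", "x", "y"])
    _CACHE[key] = df
    return df.copy()


def positions_for(labels, n_channels_hint: int | None = None) -> np.ndarray:
    """Unit-circle (x, y) for each label; NaN for unknown/non-EEG labels."""
    all_pos = _standard_positions()
    out = np.full((len(labels), 2), np.nan)
    for i, lab in enumerate(labels):
        lab_u = str(lab).upper()
        if lab_u in all_pos:
            out[i] = _project_azimuthal(all_pos[lab_u])
    return out


def occipito_parietal_roster(available_labels) -> list[str]:
    """Subset of the classifier channel roster present in ``available_labels``."""
    avail = {str(x).upper() for x in available_labels}
    return [lab for lab in OCCIPITO_PARIETAL if lab in avail]
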