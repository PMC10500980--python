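"""Unit conventions.

All public interfaces accept frequencies, damping factors and spectral ranges
in eV; internally everything is carried in Hartree atomic units.
"""

HARTREE_EV = 27.211386
SPEED_OF_LIGHT_AU = 137.035999


def ev_to_au(x):
    return x / HARTREE_EV


def au_to_ev(x):
    return x * HARTREE_EV
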