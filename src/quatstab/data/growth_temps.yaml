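# Default optimal growth temperatures (degrees C) for the TrmI crystal
# structure entries, keyed by PDB code. Ranges are represented by their
# midpoint. Used to order comparative-report rows unless overridden.
2B25: 37.0     # H. sapiens (mesophile)
1I9G: 37.0     # M. tuberculosis (mesophile)
2PWY: 70.0     # T. thermophilus (thermophile)
1O54: 78.5     # T. maritima (77-80)
2YVL: 90.5     # A. aeolicus (85-96)
3LHD: 101.5    # P. abyssi (100-103)
3LGA: 101.5    # P. abyssi
3MB5: 101.5    # P. abyssi
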