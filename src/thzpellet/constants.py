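"""Physical constants in the package's internal unit system.

All lengths are millimetres, times picoseconds, frequencies THz. With those
units the vacuum speed of light is simply its SI value scaled: mm/ps.
Absorption coefficients are carried in cm^-1 at module boundaries (the unit
THz spectroscopists plot), i.e. 10x their mm^-1 value.
"""

#: speed of light, mm/ps (== 1e-3 * c in m/s * 1e-12)
C_MM_PS: float = 0.299792458
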