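"""Physical constants in the package's working units (µm, fs/ps, nm)."""

#: speed of light in vacuum, µm per femtosecond
C_UM_PER_FS = 0.299792458

#: speed of light in vacuum, µm per picosecond
C_UM_PER_PS = 299.792458
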