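# Whole-brain 0.8 mm isotropic two-inversion 3D-EPI protocol.
# Times in ms, angles in degrees.  Lines are "key = value"; '#' is a comment.

TI1     = 800        # inversion to k-space-centre excitation, block 1 (assumed)
TI2     = 2700       # inversion to k-space-centre excitation, block 2 (assumed)
TR_IR   = 3800       # inversion-recovery cycle duration
alpha1  = 12         # excitation flip angle, TI-block 1 (design-derived)
alpha2  = 4          # excitation flip angle, TI-block 2 (design-derived)
seg     = 14         # segmentation factor (shots per volume per TI)
Rz      = 3          # CAIPI undersampling along kz
pF      = 0.75       # phase partial Fourier (6/8)
N       = 232 232 186
n_combo = 4          # read/phase polarity combinations
eps_inv = 1.0        # inversion efficiency
esp_eff = 0.10       # effective echo spacing along PE after interleaving (ms)
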