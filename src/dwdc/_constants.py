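"""Centralized numeric conventions.

All images are handled as floating point on an 8-bit-equivalent scale: the
working peak intensity is ``MAX_INTENSITY`` = 255 regardless of the source
bit depth. PSNR/SSIM default their peak to this constant, and degradation
clips into [0, MAX_INTENSITY].
"""

MAX_INTENSITY: float = 255.0

#: floor applied to the Richardson-Lucy ratio denominator (masks contain exact zeros)
RL_EPS: float = 1e-12
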