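# Synthetic placeholder wear-coefficient tables C(CSR).
#
# The wear law W = C * A * S takes a non-dimensional coefficient C that is
# a function of the cross-shear ratio, determined experimentally from
# multidirectional pin-on-plate tests.  The published pin-on-plate tables
# for these two materials are not reproduced here; the tables below are
# synthetic placeholders with the qualitative features such data show —
# a small non-zero coefficient under unidirectional sliding (CSR = 0), a
# steep rise at low cross-shear, and saturation — with magnitudes chosen so
# that whole-joint wear rates land in the physiological few-mm^3-per-
# million-cycles range.  The cross-linked material wears several-fold less
# at every cross-shear level.  Substitute measured tables for quantitative
# work.  Interpolation between rows is linear in log(C).
maps:
  GVF:
    material: conventional
    csr: [0.0, 0.001, 0.002, 0.005, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5]
    c:
      [2.0e-11, 1.2e-10, 2.5e-10, 6.0e-10, 1.2e-09, 2.2e-09, 3.8e-09,
       4.8e-09, 5.6e-09, 6.0e-09]
  XLK:
    material: moderately_crosslinked
    csr: [0.0, 0.001, 0.002, 0.005, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5]
    c:
      [4.0e-12, 2.5e-11, 5.5e-11, 1.3e-10, 2.6e-10, 4.8e-10, 8.4e-10,
       1.1e-09, 1.25e-09, 1.4e-09]
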