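# Versioned default constants of the four-element Hill-type muscle model and
# of the metabolic heat-rate accounting.
#
# The contraction-curve shapes follow the open-source macroscopic muscle model
# family (exponential isometric force-length bell, Hill hyperbola with an
# eccentric branch, nonlinear-then-linear tendon, force-dependent serial
# damping).  The heat-rate coefficients follow the published
# activation/maintenance + shortening/lengthening accounting for mixed
# fiber-type muscle.  All of these are reconstructions of the model family the
# study builds on, shipped here as one reviewable document; none of them is a
# subject-specific quantity.
version: 1

curves:
  # CE isometric force-length bell  F_isom = exp(-|(l/l_opt - 1)/dw|^nu)
  dw_des: 0.45      # width of the descending limb (dimensionless)
  nu_des: 1.5       # exponent, descending limb
  dw_asc: 0.45      # width of the ascending limb
  nu_asc: 3.0       # exponent, ascending limb
  # CE force-velocity, eccentric branch
  f_ecc: 1.5        # asymptotic eccentric force / isometric force
  s_ecc: 2.0        # eccentric/concentric slope ratio at zero velocity
  # PEE
  l_pee0: 0.95      # PEE slack length / l_CE_opt
  nu_pee: 2.5       # PEE exponent
  f_pee: 2.0        # PEE force at l_CE = l_CE_opt*(1+dw_des), relative to Fmax
  # SEE (tendon): quadratic-like toe region, then linear
  du_see_nll: 0.0425  # relative stretch at the nonlinear->linear transition
  du_see_l: 0.017     # relative stretch in the linear part at force df_see0
  rel_df_see0: 0.4    # SEE force at the toe/linear transition, relative to Fmax
  # SDE (serial damping)
  d_sde: 0.3        # max damping, relative to Fmax*A_rel0/(l_CE_opt*B_rel0)
  r_sde: 0.01       # force-independent fraction of the damping coefficient

energetics:
  am_rate_base: 25.0     # fully-active activation+maintenance heat, slow-twitch (W/kg)
  am_rate_ft_slope: 1.28 # additional heat per %FT (W/kg per percent fast-twitch)
  exp_heat_a: 0.6        # activation exponent of the A/M heat rate
  exp_short_a: 2.0       # activation exponent of the shortening heat rate
  exp_len_a: 1.0         # activation exponent of the lengthening heat rate
  vmax_ft: 12.0          # max shortening velocity, fast fibers (l_CE_opt / s)
  vmax_st_ratio: 2.5     # vmax_ft / vmax_st
  alpha_s_st_num: 100.0  # slow-twitch shortening heat coefficient numerator (W/kg)
  alpha_s_ft_num: 153.0  # fast-twitch shortening heat coefficient numerator (W/kg)
  alpha_len_factor: 4.0  # lengthening coefficient = factor * alpha_s_st
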