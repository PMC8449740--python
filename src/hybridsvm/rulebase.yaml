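# Fuzzy self-tuning PSO: crisp output levels and the rule table.
#
# Inputs:
#   delta -- Euclidean distance from a particle to the global best,
#            with linguistic labels Same / Near / Far (trapezoid/triangle
#            memberships, breakpoints 0.2/0.4/0.6 of the search-space
#            diagonal).
#   phi   -- normalized, step-scaled fitness increment in [-1, 1], with
#            labels Better / Same / Worse (negative phi = improvement).
#
# Outputs and their Low/Medium/High crisp levels (Sugeno defuzzification
# takes the activation-weighted mean of the fired levels):
levels:
  w:     {Low: 0.3, Medium: 0.5,   High: 1.0}   # inertia weight
  c_soc: {Low: 1.0, Medium: 2.0,   High: 3.0}   # social factor
  c_cog: {Low: 0.1, Medium: 1.5,   High: 3.0}   # cognitive factor
  lam:   {Low: 0.0, Medium: 0.001, High: 0.01}  # min-velocity coefficient
  eta:   {Low: 0.1, Medium: 0.15,  High: 0.2}   # max-velocity coefficient

# Rule table: one consequent level per (input label, output variable).
# Qualitative design: an improving particle keeps its momentum and trusts
# its own memory; a worsening or distant particle is pulled toward the
# global best with larger velocity caps; a particle near the global best
# takes small, careful steps.
rules:
  - {input: phi, label: Better, output: w,     level: High}
  - {input: phi, label: Same,   output: w,     level: Medium}
  - {input: phi, label: Worse,  output: w,     level: Low}
  - {input: delta, label: Same, output: w,     level: Low}
  - {input: delta, label: Near, output: w,     level: Medium}
  - {input: delta, label: Far,  output: w,     level: High}

  - {input: phi, label: Better, output: c_soc, level: Low}
  - {input: phi, label: Same,   output: c_soc, level: Medium}
  - {input: phi, label: Worse,  output: c_soc, level: High}
  - {input: delta, label: Same, output: c_soc, level: Medium}
  - {input: delta, label: Near, output: c_soc, level: Medium}
  - {input: delta, label: Far,  output: c_soc, level: High}

  - {input: phi, label: Better, output: c_cog, level: High}
  - {input: phi, label: Same,   output: c_cog, level: Medium}
  - {input: phi, label: Worse,  output: c_cog, level: Low}
  - {input: delta, label: Same, output: c_cog, level: Medium}
  - {input: delta, label: Near, output: c_cog, level: High}
  - {input: delta, label: Far,  output: c_cog, level: Low}

  - {input: phi, label: Better, output: lam,   level: Low}
  - {input: phi, label: Same,   output: lam,   level: Medium}
  - {input: phi, label: Worse,  output: lam,   level: High}
  - {input: delta, label: Same, output: lam,   level: Low}
  - {input: delta, label: Near, output: lam,   level: Medium}
  - {input: delta, label: Far,  output: lam,   level: High}

  - {input: phi, label: Better, output: eta,   level: Low}
  - {input: phi, label: Same,   output: eta,   level: Medium}
  - {input: phi, label: Worse,  output: eta,   level: High}
  - {input: delta, label: Same, output: eta,   level: Low}
  - {input: delta, label: Near, output: eta,   level: Medium}
  - {input: delta, label: Far,  output: eta,   level: High}
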