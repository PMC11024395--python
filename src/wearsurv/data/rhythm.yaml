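name: rhythm
terms:
  # class I antiarrhythmics
  - propafenone
  - disopyramide
  - quinidine
  - mexiletine
  - flecainide
  # class II antiarrhythmics
  - metoprolol
  - carvedilol
  - labetalol
  - nadolol
  - propranolol
  - carteolol
  - penbutolol
  - pindolol
  - atenolol
  - betaxolol
  - bisoprolol
  - esmolol
  - nebivolol
  - timolol
  # class III antiarrhythmics
  - sotalol
  - dofetilide
  # class IV antiarrhythmics
  - verapamil
  - diltiazem
  - nicardipine
  - amlodipine
  - felodipine
  - nifedipine
  - isradipine
  - nisoldipine
  # others
  - digoxin
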