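# Notification-event nouns: nominal forms of the action verbs.
name: event
terms:
  - notification
  - alert
  - alarm
  - reading
  - recording
  - warning
  - notice
  - report
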