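# German stopword profile for language detection
der die und in den von zu das mit sich des auf für ist im dem nicht ein
eine als auch es an werden aus er hat dass sie nach wird bei einer um am
sind noch wie einem über einen so zum war haben nur oder aber vor zur bis
mehr durch man sein wurde sei während unter gegen vom kann schon wenn
wurden diese dieser dieses ihre seine wir ihr uns alle studie ergebnisse
patienten studien
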