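# Spanish stopword profile for language detection
de la que el en y a los del se las por un para con no una su al lo como
más pero sus le ya o este sí porque esta entre cuando muy sin sobre también
me hasta hay donde quien desde todo nos durante todos uno les ni contra
otros ese eso ante ellos e esto mí antes algunos qué unos yo otro otras otra
él tanto esa estos mucho quienes nada muchos cual poco ella estar estas
algunas algo nosotros mi mis tú te ti tu tus ellas nosotras vosotros
fue son es ser está estudio resultados pacientes estudios fueron
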